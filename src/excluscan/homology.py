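"""Protein homolog filtering, pairwise identity and greedy clustering.

The comparative-genomics workflow around a newly identified protein family:
filter database search hits by identity and query coverage (defaults 45%
identity, 85% coverage), compute pairwise percent identities from global
(Needleman-Wunsch) alignments with BLOSUM62 and affine gap penalties, build
an all-vs-all identity matrix, and reduce redundancy with CD-HIT-style
greedy clustering (longest sequence first, first-fit to a cluster
representative at or above the identity cutoff, default 0.90).

Percent identity is counted over aligned columns after discarding terminal
overhangs (columns where one sequence has not started or has already
ended), matching the usual treatment of global protein alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinRecord",
    "HomologHit",
    "PairwiseAlignment",
    "ClusterSet",
    "filter_hits",
    "global_align",
    "identity_matrix",
    "greedy_cluster",
    "plot_identity_heatmap",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residues {sorted(bad)} "
                "(20 standard amino acids + X allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologHit:
    query: str
    subject: str
    pident: float   # percent identity, 0..100
    qcovs: float    # query coverage, 0..1

    def __post_init__(self):
        if not 0 <= self.pident <= 100:
            raise ValueError("pident must be in [0, 100]")
        if not 0 <= self.qcovs <= 1:
            raise ValueError("qcovs must be in [0, 1]")


@dataclass
class PairwiseAlignment:
    aligned_query: str
    aligned_subject: str
    score: float
    matches: int
    aligned_columns: int
    percent_identity: float


@dataclass
class ClusterSet:
    """Greedy identity clusters; each has a representative ("seed") member."""

    clusters: list  # of (representative_id, [member ids including representative])

    def membership(self) -> dict:
        return {m: rep for rep, members in self.clusters for m in members}

    def __len__(self) -> int:
        return len(self.clusters)


def filter_hits(
    hits, min_identity: float = 45.0, min_coverage: float = 0.85
):
    """Drop hits below the identity/coverage floor (boundary values retained).

    Accepts a DataFrame with ``pident``/``qcovs`` columns or an iterable of
    :class:`HomologHit`; returns the same kind. Idempotent.
    """
    if isinstance(hits, pd.DataFrame):
        keep = (hits["pident"] >= min_identity) & (hits["qcovs"] >= min_coverage)
        return hits[keep].reset_index(drop=True)
    return [h for h in hits if h.pident >= min_identity and h.qcovs >= min_coverage]


def _make_matrix(name: str):
    m = substitution_matrices.load(name)
    m = m.copy()
    if "X" in m.alphabet:
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


def _aligner(matrix, gap_open: float, gap_extend: float, match: float, mismatch: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(matrix, str):
        matrix = _make_matrix(matrix)
    if matrix is None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    else:
        aligner.substitution_matrix = matrix
    # a gap of length L costs gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _identity_from_strings(a: str, b: str) -> tuple[int, int, float]:
    """(matches, aligned columns, percent identity), terminal gaps excluded."""
    assert len(a) == len(b)
    n = len(a)
    # first/last column where both sequences have started/not ended
    a_res = [i for i, c in enumerate(a) if c != "-"]
    b_res = [i for i, c in enumerate(b) if c != "-"]
    start = max(a_res[0], b_res[0])
    end = min(a_res[-1], b_res[-1]) + 1
    matches = cols = 0
    for i in range(start, end):
        cols += 1
        if a[i] == b[i] and a[i] != "-":
            matches += 1
    pct = 100.0 * matches / cols if cols else 0.0
    return matches, cols, pct


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix="BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties.

    Gap scoring: a run of L gaps costs ``gap_open + (L - 1) * gap_extend``;
    ``gap_open == gap_extend`` gives linear gaps. With ``matrix=None``,
    simple ``match``/``mismatch`` scoring is used instead of a substitution
    matrix; with BLOSUM62 (default), X scores 0 against every residue.
    Percent identity is matches over aligned columns, excluding
    terminal-overhang columns.
    """
    aligner = _aligner(matrix, gap_open, gap_extend, match, mismatch)
    aln = aligner.align(a.sequence, b.sequence)[0]
    qa, sa = str(aln[0]), str(aln[1])
    matches, cols, pct = _identity_from_strings(qa, sa)
    return PairwiseAlignment(
        aligned_query=qa,
        aligned_subject=sa,
        score=float(aln.score),
        matches=matches,
        aligned_columns=cols,
        percent_identity=pct,
    )


def percent_identity(a: ProteinRecord, b: ProteinRecord, **kwargs) -> float:
    return global_align(a, b, **kwargs).percent_identity


def identity_matrix(records, **kwargs) -> pd.DataFrame:
    """All-vs-all percent identities; symmetric with a diagonal of 100."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")
    m = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            pct = percent_identity(records[i], records[j], **kwargs)
            m.iloc[i, j] = m.iloc[j, i] = pct
    return m


def greedy_cluster(records, cutoff: float = 0.90, **kwargs) -> ClusterSet:
    """CD-HIT-style greedy incremental clustering.

    Records are visited longest-first (ties broken by id); each joins the
    first existing cluster whose representative it matches at
    ``identity / 100 >= cutoff``, else founds a new cluster with itself as
    representative. Input order does not affect the result.
    """
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for rep, mem in zip(reps, members):
            if percent_identity(rec, rep, **kwargs) / 100.0 >= cutoff:
                mem.append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return ClusterSet(clusters=[(rep.id, mem) for rep, mem in zip(reps, members)])


def plot_identity_heatmap(matrix: pd.DataFrame, path) -> None:
    """Write a percent-identity heatmap (pairwise homolog comparison figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(matrix) + 3, 0.5 * len(matrix) + 2.5))
    im = ax.imshow(matrix.to_numpy(), cmap="magma", vmin=0, vmax=100)
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix)), matrix.index)
    fig.colorbar(im, ax=ax, label="% identity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
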