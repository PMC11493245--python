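"""Scoring of a transposon-directed insertion sequencing (TraDIS) screen.

The screen compares two Tn5 insertion libraries in the same strain: the
input library (all viable mutants) and the output library (mutants that
passed a selection, here acquisition of a mobilized plasmid during
conjugation). Genes whose disruption relieves a block on plasmid entry are
over-represented among output insertions.

Processing stages:

1. :func:`match_and_trim_tag` — keep reads whose leading bases match the
   inline transposon tag (within a mismatch budget) and strip the tag.
2. :func:`map_insertions` — place each read's junction on the reference by a
   unique-best exact match of its leading seed k-mer, on either strand, with
   circular wrap-around; ambiguous and unmatched reads are discarded and
   counted.
3. :func:`compute_insertion_index` — per-gene unique insertion sites per bp,
   normalized by the library's total unique sites so libraries of different
   depth are comparable.
4. :func:`call_candidates` — output/input index ratio per gene with a plain
   threshold (default 5), the screen's candidate call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import (
    GeneAnnotation,
    InsertionLibrary,
    ReadSet,
    ReferenceAssembly,
    _revcomp,
)

__all__ = [
    "TagStats",
    "InsertionSiteSet",
    "match_and_trim_tag",
    "map_insertions",
    "sites_from_library",
    "compute_insertion_index",
    "call_candidates",
    "run_screen",
]


@dataclass
class TagStats:
    kept: int = 0
    discarded: int = 0


@dataclass
class InsertionSiteSet:
    """Distinct insertion sites with read support.

    ``sites`` columns: replicon, position, strand, read_count; one row per
    (replicon, position, strand) key. Mapping bookkeeping lives in
    ``mapped`` / ``unmatched`` / ``ambiguous``.
    """

    sites: pd.DataFrame
    label: str = "input"
    mapped: int = 0
    unmatched: int = 0
    ambiguous: int = 0

    def __post_init__(self):
        if len(self.sites):
            if (self.sites["read_count"] < 1).any():
                raise ValueError("read_count must be >= 1")
            if self.sites.duplicated(["replicon", "position", "strand"]).any():
                raise ValueError("site keys must be unique")

    def __len__(self) -> int:
        return len(self.sites)


def match_and_trim_tag(reads: ReadSet, tag: str, max_mismatches: int = 0):
    """Filter reads by the inline transposon tag and strip it.

    Returns ``(trimmed ReadSet, TagStats)``. A read is kept iff its leading
    ``len(tag)`` bases match the tag with at most ``max_mismatches``
    substitutions.
    """
    if not tag:
        raise ValueError("tag must be non-empty")
    if any(len(bases) < len(tag) for _, bases, _ in reads):
        raise ValueError("tag longer than at least one read")

    n = len(tag)
    stats = TagStats()
    kept = []
    for rid, bases, quals in reads:
        mism = sum(a != b for a, b in zip(bases[:n], tag))
        if mism <= max_mismatches:
            kept.append((rid, bases[n:], quals[n:]))
            stats.kept += 1
        else:
            stats.discarded += 1
    return (
        ReadSet(reads=kept, tag="", read_length=reads.read_length - n, error_rate=reads.error_rate),
        stats,
    )


_AMBIGUOUS = object()


def _build_seed_index(ref: ReferenceAssembly, k: int) -> dict:
    """k-mer -> unique (replicon, junction_position, strand), both strands.

    The stored position is the junction base the site convention reports: the
    k-mer's first reference base for a forward hit, its last for a
    reverse-complement hit. Circular replicons contribute origin-spanning
    k-mers with positions taken modulo the length. Any k-mer seen at two or
    more loci is marked ambiguous.
    """
    index: dict = {}
    for rep in ref:
        L = len(rep)
        seq = rep.sequence + (rep.sequence[: k - 1] if rep.circular else "")
        n_start = L if rep.circular else L - k + 1
        for o in range(max(n_start, 0)):
            kmer = seq[o : o + k]
            if len(kmer) < k:
                continue
            for key, site in (
                (kmer, (rep.name, o % L, "+")),
                (_revcomp(kmer), (rep.name, (o + k - 1) % L, "-")),
            ):
                if key in index and index[key] != site:
                    index[key] = _AMBIGUOUS
                elif key not in index:
                    index[key] = site
    return index


def map_insertions(
    trimmed: ReadSet, ref: ReferenceAssembly, seed_length: int = 25, label: str = "input"
) -> InsertionSiteSet:
    """Locate each read's junction by unique-best exact seed match.

    The leading ``seed_length`` bases of each (tag-trimmed) read are looked
    up on both strands of the reference; a unique exact hit yields a site at
    the junction base on the matching strand, ambiguous (two or more loci)
    and unmatched seeds are discarded and counted.
    """
    if not ref.replicons:
        raise ValueError("reference assembly is empty")
    if any(len(bases) < seed_length for _, bases, _ in trimmed):
        raise ValueError("post-tag read length shorter than seed_length")

    index = _build_seed_index(ref, seed_length)
    counts: dict = {}
    unmatched = ambiguous = 0
    for _, bases, _ in trimmed:
        site = index.get(bases[:seed_length])
        if site is None:
            unmatched += 1
        elif site is _AMBIGUOUS:
            ambiguous += 1
        else:
            counts[site] = counts.get(site, 0) + 1

    rows = [
        {"replicon": r, "position": p, "strand": s, "read_count": c}
        for (r, p, s), c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["replicon", "position", "strand", "read_count"])
    return InsertionSiteSet(
        sites=df,
        label=label,
        mapped=len(trimmed) - unmatched - ambiguous,
        unmatched=unmatched,
        ambiguous=ambiguous,
    )


def sites_from_library(lib: InsertionLibrary) -> InsertionSiteSet:
    """View a simulated insertion library directly as a site set.

    Shortcut past read synthesis/mapping: abundances become read counts.
    """
    df = lib.sites.rename(columns={"abundance": "read_count"})
    df = df[df["read_count"] >= 1].reset_index(drop=True)
    return InsertionSiteSet(sites=df, label=lib.label, mapped=int(df["read_count"].sum()))


def compute_insertion_index(sites: InsertionSiteSet, annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-gene insertion indices.

    For gene *g* of length *L_g* with *u_g* distinct insertion sites inside
    ``[start, end)``: raw density ``u_g / L_g`` and normalized insertion
    index ``u_g / L_g / U`` where *U* is the library's total number of
    distinct sites (intergenic included). Columns: gene_id, replicon, start,
    end, length, unique_sites, raw_density, insertion_index, label.
    """
    if not len(annotation):
        raise ValueError("annotation is empty")

    total = len(sites.sites)
    rows = []
    site_df = sites.sites
    for row in annotation.genes.itertuples(index=False):
        in_gene = site_df[
            (site_df["replicon"] == row.replicon)
            & (site_df["position"] >= row.start)
            & (site_df["position"] < row.end)
        ]
        u = len(in_gene)
        length = row.end - row.start
        raw = u / length
        rows.append(
            {
                "gene_id": row.gene_id,
                "replicon": row.replicon,
                "start": row.start,
                "end": row.end,
                "length": length,
                "unique_sites": u,
                "raw_density": raw,
                "insertion_index": raw / total if total else 0.0,
                "label": sites.label,
            }
        )
    return pd.DataFrame(rows)


def call_candidates(
    input_idx: pd.DataFrame,
    output_idx: pd.DataFrame,
    threshold: float = 5.0,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Output/input insertion-index ratios with a plain candidate threshold.

    ``R_g = (output_index + c) / (input_index + c)`` with pseudocount *c*
    defaulting to half the smallest nonzero normalized index across both
    libraries (0 if every index is zero). A gene is a candidate iff
    ``R_g > threshold`` — the threshold is deliberately arbitrary, as in the
    original screen. Genes missing from one table are treated as index 0 and
    flagged. Rows are ordered by genomic coordinate.
    """
    inp = input_idx.set_index("gene_id")
    out = output_idx.set_index("gene_id")
    genes = inp.index.union(out.index)
    coord = pd.concat([inp, out])[["replicon", "start"]]
    coord = coord[~coord.index.duplicated()]

    in_vals = inp["insertion_index"].reindex(genes, fill_value=0.0)
    out_vals = out["insertion_index"].reindex(genes, fill_value=0.0)
    flagged = (~genes.isin(inp.index)) | (~genes.isin(out.index))

    if pseudocount is None:
        nonzero = pd.concat([in_vals, out_vals])
        nonzero = nonzero[nonzero > 0]
        pseudocount = 0.5 * nonzero.min() if len(nonzero) else 0.0

    ratio = (out_vals + pseudocount) / (in_vals + pseudocount)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "replicon": coord["replicon"].reindex(genes),
            "start": coord["start"].reindex(genes),
            "input_index": in_vals.to_numpy(),
            "output_index": out_vals.to_numpy(),
            "ratio": ratio.to_numpy(),
            "candidate": (ratio > threshold).to_numpy(),
            "flagged": flagged,
            "threshold": threshold,
            "pseudocount": pseudocount,
        }
    )
    return table.sort_values(["replicon", "start"], ignore_index=True)


def run_screen(
    input_reads: ReadSet,
    output_reads: ReadSet,
    ref: ReferenceAssembly,
    annotation: GeneAnnotation,
    tag: str,
    max_mismatches: int = 0,
    seed_length: int = 25,
    threshold: float = 5.0,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Full screen: tag trim, map, index and call candidates for two read sets."""
    tables = {}
    for label, reads in (("input", input_reads), ("output", output_reads)):
        trimmed, _ = match_and_trim_tag(reads, tag, max_mismatches)
        sites = map_insertions(trimmed, ref, seed_length=seed_length, label=label)
        tables[label] = compute_insertion_index(sites, annotation)
    return call_candidates(
        tables["input"], tables["output"], threshold=threshold, pseudocount=pseudocount
    )
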