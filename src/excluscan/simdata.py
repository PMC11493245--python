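"""Synthetic data for transposon-insertion screens of conjugative plasmids.

This module emulates, at desk scale, the experiment in which a dense mini-Tn5
insertion library in a plasmid-bearing recipient strain is mated with a donor
carrying a mobilizable plasmid: mutants whose disrupted gene normally impedes
plasmid acquisition (an exclusion gene) acquire the incoming plasmid more
often and are enriched in the post-selection ("output") library relative to
the pre-selection ("input") library.

It generates

* a small multi-replicon reference (chromosome + plasmid) with non-overlapping
  annotated ORFs,
* near-uniform Tn5 insertion libraries over that reference,
* output libraries produced by per-mutant Bernoulli selection whose success
  probability is multiplied for insertions that disrupt designated genes,
* single-end transposon-junction reads (inline tag + genomic junction) with an
  i.i.d. substitution error process, and
* CFU tables of mating assays with planted exclusion patterns, for exercising
  the conjugation statistics downstream.

All randomness flows through :func:`numpy.random.default_rng` seeds, so every
generator is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Replicon",
    "ReferenceAssembly",
    "GeneAnnotation",
    "InsertionLibrary",
    "SelectionModel",
    "ReadSet",
    "generate_reference",
    "simulate_insertion_library",
    "apply_conjugation_selection",
    "synthesize_reads",
    "simulate_mating_assay",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Replicon:
    """A single reference sequence (chromosome or plasmid)."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"replicon {self.name!r}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"replicon {self.name!r}: alphabet must be ACGT")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceAssembly:
    """An ordered collection of uniquely named replicons."""

    replicons: tuple[Replicon, ...]

    def __post_init__(self):
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            raise ValueError("replicon names must be unique")

    def __iter__(self):
        return iter(self.replicons)

    def get(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.replicons)


@dataclass(frozen=True)
class GeneAnnotation:
    """ORF coordinates, 0-based half-open, on named replicons.

    The on-disk GFF3 representation is 1-based inclusive; conversion happens
    in :mod:`excluscan.io`.
    """

    genes: pd.DataFrame  # columns: gene_id, replicon, start, end, strand

    def __post_init__(self):
        df = self.genes
        required = {"gene_id", "replicon", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation must have columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValueError("require 0 <= start < end for every gene")

    def __len__(self) -> int:
        return len(self.genes)

    def lengths(self) -> pd.Series:
        s = (self.genes["end"] - self.genes["start"]).astype(int)
        s.index = self.genes["gene_id"]
        return s

    def validate_against(self, ref: ReferenceAssembly) -> None:
        for rep_name, sub in self.genes.groupby("replicon"):
            if (sub["end"] > len(ref.get(rep_name))).any():
                raise ValueError(f"gene extends past end of replicon {rep_name!r}")


@dataclass
class InsertionLibrary:
    """Tn5 insertion sites with mutant abundances.

    ``sites`` has columns replicon, position, strand, abundance; one row per
    distinct (replicon, position, strand) key. ``label`` distinguishes the
    pre-selection input library from the post-selection output library.
    """

    sites: pd.DataFrame
    label: str = "input"

    def __post_init__(self):
        required = {"replicon", "position", "strand", "abundance"}
        if not required.issubset(self.sites.columns):
            raise ValueError(f"library must have columns {sorted(required)}")
        if (self.sites["abundance"] < 0).any():
            raise ValueError("abundances must be non-negative")
        if len(self.sites) and self.sites["abundance"].sum() <= 0:
            raise ValueError("non-empty library must have positive total abundance")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def total_abundance(self) -> int:
        return int(self.sites["abundance"].sum())


@dataclass(frozen=True)
class SelectionModel:
    """Per-gene modifiers of the probability of acquiring the mobilized plasmid.

    ``base_rate`` is the acquisition probability of an unaffected mutant;
    disrupting gene *g* multiplies it by ``effects[g]`` (>1 for exclusion
    genes, whose loss relieves the block on incoming transfer). The product is
    clamped to 1 at sampling time.
    """

    base_rate: float
    effects: dict = field(default_factory=dict)
    intergenic_multiplier: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be in [0, 1]")
        if any(e < 0 for e in self.effects.values()) or self.intergenic_multiplier < 0:
            raise ValueError("effect multipliers must be >= 0")


@dataclass
class ReadSet:
    """Single-end transposon-junction reads (FASTQ-ready).

    Each read is the inline transposon ``tag`` followed by genomic sequence
    extending 3'-ward from the insertion point on the recorded strand, with
    i.i.d. substitution errors at ``error_rate`` per base.
    """

    reads: list  # of (id, bases, qualities) str triples
    tag: str
    read_length: int
    error_rate: float

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def generate_reference(
    n_genes: int,
    gene_length_range: tuple[int, int] = (300, 900),
    intergenic_length: int = 100,
    plasmid_fraction: float = 0.2,
    seed: int | None = None,
) -> tuple[ReferenceAssembly, GeneAnnotation]:
    """Generate a two-replicon reference (chromosome + plasmid) with ORFs.

    Genes alternate with fixed-length intergenic spacers, never overlap, and
    are split between the replicons: ``round(n_genes * plasmid_fraction)``
    genes go to the circular plasmid, the rest to the chromosome. Gene
    lengths are drawn uniformly from ``gene_length_range`` (inclusive) and
    strands uniformly. Deterministic for a fixed seed.
    """
    lo, hi = gene_length_range
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if lo <= 0 or hi <= 0 or lo > hi or intergenic_length <= 0:
        raise ValueError("gene and intergenic lengths must be positive (lo <= hi)")
    if not 0.0 <= plasmid_fraction <= 1.0:
        raise ValueError("plasmid_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_plasmid = int(round(n_genes * plasmid_fraction))
    n_chrom = n_genes - n_plasmid

    replicons = []
    rows = []
    for rep_name, prefix, n in (("chromosome", "c", n_chrom), ("plasmid", "p", n_plasmid)):
        parts = [_random_dna(rng, intergenic_length)]
        pos = intergenic_length
        for i in range(n):
            glen = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(_random_dna(rng, glen))
            rows.append(
                {
                    "gene_id": f"orf_{prefix}{i + 1:03d}",
                    "replicon": rep_name,
                    "start": pos,
                    "end": pos + glen,
                    "strand": strand,
                }
            )
            pos += glen
            parts.append(_random_dna(rng, intergenic_length))
            pos += intergenic_length
        replicons.append(Replicon(rep_name, "".join(parts), circular=True))

    annotation = GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "replicon", "start", "end", "strand"])
    )
    assembly = ReferenceAssembly(tuple(replicons))
    annotation.validate_against(assembly)
    return assembly, annotation


def simulate_insertion_library(
    ref: ReferenceAssembly, n_mutants: int, seed: int | None = None
) -> InsertionLibrary:
    """Draw ``n_mutants`` insertion positions i.i.d. uniform over the genome.

    Each mutant contributes abundance 1; mutants landing on the same
    (replicon, position, strand) key are summed. Strands are uniform.
    """
    if n_mutants < 0:
        raise ValueError("n_mutants must be >= 0")
    if not ref.replicons or ref.total_length == 0:
        raise ValueError("reference assembly is empty")

    rng = np.random.default_rng(seed)
    lengths = np.array([len(r) for r in ref.replicons])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    flat = rng.integers(0, ref.total_length, size=n_mutants)
    rep_idx = np.searchsorted(offsets, flat, side="right") - 1
    positions = flat - offsets[rep_idx]
    strands = np.where(rng.random(n_mutants) < 0.5, "+", "-")

    df = pd.DataFrame(
        {
            "replicon": [ref.replicons[i].name for i in rep_idx],
            "position": positions.astype(int),
            "strand": strands,
            "abundance": 1,
        }
    )
    if len(df):
        df = (
            df.groupby(["replicon", "position", "strand"], as_index=False)["abundance"]
            .sum()
            .sort_values(["replicon", "position", "strand"], ignore_index=True)
        )
    return InsertionLibrary(sites=df, label="input")


def _gene_lookup(annotation: GeneAnnotation):
    """Per-replicon sorted interval arrays for point-in-gene queries."""
    lookup = {}
    for rep, sub in annotation.genes.groupby("replicon"):
        sub = sub.sort_values("start")
        lookup[rep] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["gene_id"].to_numpy(),
        )
    return lookup


def genes_at(annotation: GeneAnnotation, replicon: np.ndarray, position: np.ndarray) -> np.ndarray:
    """Vectorized gene-id lookup for insertion points; None for intergenic."""
    lookup = _gene_lookup(annotation)
    out = np.full(len(position), None, dtype=object)
    replicon = np.asarray(replicon)
    position = np.asarray(position)
    for rep, (starts, ends, ids) in lookup.items():
        mask = replicon == rep
        if not mask.any():
            continue
        pos = position[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        res = np.full(len(pos), None, dtype=object)
        res[valid] = ids[idx[valid]]
        out[mask] = res
    return out


def apply_conjugation_selection(
    lib: InsertionLibrary,
    model: SelectionModel,
    annotation: GeneAnnotation,
    seed: int | None = None,
) -> InsertionLibrary:
    """Select mutants that acquire the mobilized plasmid.

    Each mutant is retained independently with probability
    ``min(1, base_rate * multiplier)`` where the multiplier is the effect of
    the gene containing its insertion point (``intergenic_multiplier``
    outside genes). The output site set is a sub-multiset of the input.
    """
    if lib.label != "input":
        raise ValueError("selection applies to an input library")

    rng = np.random.default_rng(seed)
    df = lib.sites
    gene = genes_at(annotation, df["replicon"].to_numpy(), df["position"].to_numpy())
    mult = np.array(
        [
            model.effects.get(g, 1.0) if g is not None else model.intergenic_multiplier
            for g in gene
        ]
    )
    p = np.minimum(1.0, model.base_rate * mult)
    retained = rng.binomial(df["abundance"].to_numpy(), p)
    out = df.assign(abundance=retained)
    out = out[out["abundance"] > 0].reset_index(drop=True)
    return InsertionLibrary(sites=out, label="output")


def synthesize_reads(
    lib: InsertionLibrary,
    ref: ReferenceAssembly,
    tag: str = "CTGTCTCTTA",
    read_length: int = 50,
    error_rate: float = 0.0,
    depth_per_mutant: int = 10,
    seed: int | None = None,
) -> ReadSet:
    """Emit tag+junction reads for every mutant in the library.

    Each mutant yields ``depth_per_mutant`` reads: the tag followed by
    ``read_length - len(tag)`` genomic bases extending 3'-ward from the
    insertion point on the recorded strand. Circular replicons wrap modulo
    their length; reads that would run off the end of a linear replicon are
    discarded. Substitution errors hit every base (tag included) i.i.d. at
    ``error_rate``; qualities are constant Sanger 'I'.
    """
    if read_length <= len(tag):
        raise ValueError("read_length must exceed tag length")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if depth_per_mutant < 0:
        raise ValueError("depth_per_mutant must be >= 0")

    rng = np.random.default_rng(seed)
    g = read_length - len(tag)
    tag_arr = np.frombuffer(tag.encode(), dtype=np.uint8)
    qual = "I" * read_length
    # base -> 0..3 code, for vectorized complement/error handling
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i

    reads = []
    counter = 0
    for rep in ref.replicons:
        sub = lib.sites[lib.sites["replicon"] == rep.name]
        if not len(sub):
            continue
        L = len(rep)
        seq_codes = code[np.frombuffer(rep.sequence.encode(), dtype=np.uint8)]
        pos = np.repeat(sub["position"].to_numpy(), sub["abundance"].to_numpy())
        strand = np.repeat(sub["strand"].to_numpy(), sub["abundance"].to_numpy())
        pos = np.repeat(pos, depth_per_mutant)
        strand = np.repeat(strand, depth_per_mutant)
        if not len(pos):
            continue

        fwd = strand == "+"
        off = np.arange(g)
        idx = np.where(fwd[:, None], pos[:, None] + off, pos[:, None] - off)
        if rep.circular:
            idx %= L
            keep = np.ones(len(pos), dtype=bool)
        else:
            keep = ((idx >= 0) & (idx < L)).all(axis=1)
            idx = np.clip(idx, 0, L - 1)
        genomic = seq_codes[idx]
        genomic[~fwd] = 3 - genomic[~fwd]  # complement for minus-strand reads

        n = len(pos)
        full = np.empty((n, read_length), dtype=np.uint8)
        full[:, : len(tag)] = code[tag_arr]
        full[:, len(tag):] = genomic
        if error_rate > 0:
            err = rng.random((n, read_length)) < error_rate
            shift = rng.integers(1, 4, size=int(err.sum()))
            full[err] = (full[err] + shift) % 4
        letters = _BASES[full]
        for i in range(n):
            if not keep[i]:
                continue
            reads.append(
                (
                    f"read_{counter:07d} {rep.name}:{pos[i]}:{strand[i]}",
                    letters[i].tobytes().decode(),
                    qual,
                )
            )
            counter += 1
    return ReadSet(reads=reads, tag=tag, read_length=read_length, error_rate=error_rate)


def simulate_mating_assay(
    sfx_variants: list[str],
    tran_variants: list[str],
    cognate_pairs: set[tuple[str, str]],
    reference_recipient: str = "empty",
    exclusion_fold: float = 100.0,
    base_frequency: float = 1e-3,
    donor_cfu: float = 1e9,
    recipient_cfu: float = 1e9,
    replicates: int = 3,
    noise_sd_log10: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthesize a CFU table for an sfx × traN surface-exclusion assay.

    For every donor traN variant, matings are simulated toward the empty
    reference recipient and toward recipients expressing each sfx variant.
    Cognate (sfx, traN) pairs transfer at ``base_frequency / exclusion_fold``;
    all other combinations at ``base_frequency``. Log-normal replicate noise
    (sd ``noise_sd_log10`` in log10 units) is applied to frequencies before
    converting to transconjugant CFU counts.

    Returns the mating CSV schema used downstream: donor, recipient,
    replicate, donor_cfu, recipient_cfu, transconjugant_cfu, sfx_variant,
    traN_variant.
    """
    rng = np.random.default_rng(seed)
    rows = []
    recipients = [reference_recipient] + list(sfx_variants)
    for t in tran_variants:
        for s in recipients:
            excluded = s != reference_recipient and (s, t) in cognate_pairs
            freq = base_frequency / exclusion_fold if excluded else base_frequency
            for rep_i in range(1, replicates + 1):
                noisy = freq * 10 ** rng.normal(0.0, noise_sd_log10)
                tc = float(np.round(noisy * donor_cfu))
                rows.append(
                    {
                        "donor": f"donor_{t}",
                        "recipient": s,
                        "replicate": rep_i,
                        "donor_cfu": donor_cfu,
                        "recipient_cfu": recipient_cfu,
                        "transconjugant_cfu": tc,
                        "sfx_variant": s,
                        "traN_variant": t,
                    }
                )
    return pd.DataFrame(rows)
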