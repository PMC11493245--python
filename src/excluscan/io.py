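"""Readers and writers for the plain-text formats used across the package.

FASTA and FASTQ go through Biopython; GFF3 and the tabular formats are plain
pandas. Coordinates are 0-based half-open in memory and 1-based inclusive in
GFF3 on disk.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import GeneAnnotation, InsertionLibrary, ReadSet, Replicon, ReferenceAssembly

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_fastq",
    "read_fastq",
    "write_library_tsv",
    "read_library_tsv",
    "read_mating_csv",
    "read_protein_fasta",
    "read_blast_tab",
]


def write_fasta(ref: ReferenceAssembly, path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.name,
            description=f"circular={'true' if r.circular else 'false'}",
        )
        for r in ref
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> ReferenceAssembly:
    reps = []
    for rec in SeqIO.parse(path, "fasta"):
        circular = "circular=true" in rec.description
        reps.append(Replicon(rec.id, str(rec.seq).upper(), circular=circular))
    return ReferenceAssembly(tuple(reps))


def write_gff3(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.genes.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.replicon,
                        "excluscan",
                        "gene",
                        str(row.start + 1),  # GFF3 is 1-based inclusive
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        f"ID={row.gene_id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> GeneAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "replicon",
            "source",
            "type",
            "start",
            "end",
            "score",
            "strand",
            "phase",
            "attributes",
        ],
    )
    df = df[df["type"] == "gene"].copy()
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "gene_id": ids,
            "replicon": df["replicon"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "strand": df["strand"],
        }
    ).reset_index(drop=True)
    return GeneAnnotation(out)


def write_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for rid, bases, quals in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{quals}\n")


def read_fastq(path, tag: str = "", error_rate: float = 0.0) -> ReadSet:
    triples = []
    read_length = 0
    for rec in SeqIO.parse(path, "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        desc = rec.description if rec.description != rec.id else rec.id
        triples.append((desc, str(rec.seq), quals))
        read_length = max(read_length, len(rec.seq))
    return ReadSet(reads=triples, tag=tag, read_length=read_length, error_rate=error_rate)


def write_library_tsv(lib: InsertionLibrary, path) -> None:
    lib.sites.to_csv(path, sep="\t", index=False)


def read_library_tsv(path, label: str = "input") -> InsertionLibrary:
    df = pd.read_csv(path, sep="\t")
    return InsertionLibrary(sites=df, label=label)


def read_mating_csv(path) -> pd.DataFrame:
    """Read a CFU table.

    Required columns: donor, recipient, replicate, donor_cfu, recipient_cfu,
    transconjugant_cfu. Optional: sfx_variant, traN_variant (for the
    exclusion-matrix workflow).
    """
    df = pd.read_csv(path)
    required = {
        "donor",
        "recipient",
        "replicate",
        "donor_cfu",
        "recipient_cfu",
        "transconjugant_cfu",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mating CSV missing columns: {sorted(missing)}")
    return df


def read_protein_fasta(path) -> list:
    from .homology import ProteinRecord

    return [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def read_blast_tab(path) -> pd.DataFrame:
    """Read a BLAST-style tabular hit file with query/subject/pident/qcovs."""
    df = pd.read_csv(path, sep="\t")
    alias = {"qseqid": "query", "sseqid": "subject"}
    df = df.rename(columns=alias)
    required = {"query", "subject", "pident", "qcovs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df
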