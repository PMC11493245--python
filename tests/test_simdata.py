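"""Generators: determinism, geometry, uniformity, selection and read synthesis."""

import numpy as np
import pandas as pd
import pytest

from excluscan import (
    GeneAnnotation,
    InsertionLibrary,
    ReferenceAssembly,
    Replicon,
    SelectionModel,
    apply_conjugation_selection,
    generate_reference,
    io,
    simulate_insertion_library,
    simulate_mating_assay,
    synthesize_reads,
)


class TestGenerateReference:
    def test_empty_annotation_for_zero_genes(self):
        ref, ann = generate_reference(0, seed=0)
        assert len(ann) == 0
        assert all(len(r) > 0 for r in ref)

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        for i, d in enumerate(("a", "b")):
            ref, ann = generate_reference(12, seed=7)
            (tmp_path / d).mkdir()
            io.write_fasta(ref, tmp_path / d / "ref.fasta")
            io.write_gff3(ann, tmp_path / d / "genes.gff3")
        for name in ("ref.fasta", "genes.gff3"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_annotated_span_matches_gff3_roundtrip(self, tmp_path):
        """Total annotated span recomputed independently from the emitted GFF3."""
        ref, ann = generate_reference(10, gene_length_range=(300, 900), seed=3)
        path = tmp_path / "genes.gff3"
        io.write_gff3(ann, path)
        # independent summation from raw GFF3 text (1-based inclusive)
        span = 0
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            span += int(f[4]) - int(f[3]) + 1
        assert span == int((ann.genes["end"] - ann.genes["start"]).sum())
        assert all(300 <= l <= 900 for l in ann.lengths())

    def test_genes_non_overlapping_and_within_bounds(self):
        ref, ann = generate_reference(30, seed=5)
        ann.validate_against(ref)
        for _, sub in ann.genes.groupby("replicon"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gene_length_range": (0, 100)},
            {"gene_length_range": (500, 100)},
            {"intergenic_length": 0},
            {"plasmid_fraction": 1.5},
        ],
    )
    def test_bad_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            generate_reference(5, seed=0, **kwargs)


class TestInsertionLibrary:
    def test_zero_mutants_gives_empty_library(self, small_reference):
        ref, _ = small_reference
        lib = simulate_insertion_library(ref, 0, seed=0)
        assert len(lib) == 0

    def test_same_seed_reproducible(self, small_reference):
        ref, _ = small_reference
        a = simulate_insertion_library(ref, 5000, seed=9)
        b = simulate_insertion_library(ref, 5000, seed=9)
        pd.testing.assert_frame_equal(a.sites, b.sites)

    def test_gene_occupancy_matches_binomial_oracle(self):
        """A gene holding fraction f of the genome gets Binomial(n, f) mutants."""
        ref, ann = generate_reference(20, gene_length_range=(400, 600), seed=2)
        lib = simulate_insertion_library(ref, 100_000, seed=3)
        gene = ann.genes.iloc[0]
        f = (gene.end - gene.start) / ref.total_length
        n = 100_000
        in_gene = lib.sites[
            (lib.sites.replicon == gene.replicon)
            & (lib.sites.position >= gene.start)
            & (lib.sites.position < gene.end)
        ]["abundance"].sum()
        sigma = np.sqrt(n * f * (1 - f))
        assert abs(in_gene - n * f) < 4 * sigma

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            simulate_insertion_library(ReferenceAssembly(()), 10, seed=0)


class TestSelection:
    def test_output_is_submultiset_of_input(self, planted_experiment):
        _, _, lib, out, _ = planted_experiment
        merged = out.sites.merge(
            lib.sites, on=["replicon", "position", "strand"], suffixes=("_out", "_in")
        )
        assert len(merged) == len(out.sites)  # no new positions created
        assert (merged["abundance_out"] <= merged["abundance_in"]).all()
        assert out.label == "output"

    def test_zero_base_rate_empties_library(self, small_reference):
        ref, ann = small_reference
        lib = simulate_insertion_library(ref, 1000, seed=1)
        out = apply_conjugation_selection(lib, SelectionModel(base_rate=0.0), ann, seed=2)
        assert len(out) == 0

    def test_neutral_selection_keeps_base_rate_fraction(self, small_reference):
        """With all effects 1, every gene's expected retention equals base_rate."""
        ref, ann = small_reference
        lib = simulate_insertion_library(ref, 50_000, seed=4)
        out = apply_conjugation_selection(lib, SelectionModel(base_rate=0.2), ann, seed=5)
        kept = out.total_abundance / lib.total_abundance
        sigma = np.sqrt(0.2 * 0.8 / lib.total_abundance)
        assert abs(kept - 0.2) < 4 * sigma

    def test_planted_gene_enrichment_matches_analytic_expectation(self, planted_experiment):
        """Monte-Carlo abundance ratio against the closed-form retention ratio.

        An insertion in the planted gene is retained w.p. 20 * 0.01, others
        w.p. 0.01, so the gene's output share is inflated by the factor
        0.2 / (0.01 * (1 - f) + 0.2 * f) where f is its insertion share.
        """
        ref, ann, lib, out, model = planted_experiment
        gene = ann.genes.set_index("gene_id").loc["orf_p001"]

        def share(library):
            m = library.sites[
                (library.sites.replicon == gene.replicon)
                & (library.sites.position >= gene.start)
                & (library.sites.position < gene.end)
            ]["abundance"].sum()
            return m / library.total_abundance

        f_in = share(lib)
        expected = 0.2 / (0.01 * (1 - f_in) + 0.2 * f_in)
        observed = share(out) / f_in
        assert observed == pytest.approx(expected, rel=0.35)  # ~130 retained mutants

    def test_selection_requires_input_label(self, planted_experiment):
        _, ann, _, out, model = planted_experiment
        with pytest.raises(ValueError):
            apply_conjugation_selection(out, model, ann, seed=0)


class TestReads:
    def test_error_free_reads_match_reference(self, small_reference):
        ref, _ = small_reference
        lib = simulate_insertion_library(ref, 200, seed=6)
        reads = synthesize_reads(lib, ref, error_rate=0.0, depth_per_mutant=1, seed=7)
        tag = reads.tag
        for rid, bases, _ in reads:
            rep_name, pos, strand = rid.split()[1].split(":")
            rep = ref.get(rep_name)
            pos = int(pos)
            assert bases.startswith(tag)
            g = len(bases) - len(tag)
            if strand == "+":
                expect = "".join(rep.sequence[(pos + k) % len(rep)] for k in range(g))
            else:
                comp = dict(zip("ACGT", "TGCA"))
                expect = "".join(comp[rep.sequence[(pos - k) % len(rep)]] for k in range(g))
            assert bases[len(tag):] == expect

    def test_circular_wraparound(self):
        rep = Replicon("pl", "ACGT" * 25, circular=True)  # length 100
        ref = ReferenceAssembly((rep,))
        lib = InsertionLibrary(
            sites=pd.DataFrame(
                [{"replicon": "pl", "position": 95, "strand": "+", "abundance": 1}]
            )
        )
        reads = synthesize_reads(lib, ref, tag="CTGTCTCTTA", read_length=40,
                                 depth_per_mutant=1, seed=0)
        (_, bases, _), = reads.reads
        genomic = bases[10:]
        assert genomic == (rep.sequence * 2)[95:125]

    def test_linear_overhang_discarded(self):
        rep = Replicon("lin", "ACGT" * 25, circular=False)
        ref = ReferenceAssembly((rep,))
        lib = InsertionLibrary(
            sites=pd.DataFrame(
                [
                    {"replicon": "lin", "position": 95, "strand": "+", "abundance": 1},
                    {"replicon": "lin", "position": 10, "strand": "+", "abundance": 1},
                ]
            )
        )
        reads = synthesize_reads(lib, ref, tag="CTGTCTCTTA", read_length=40,
                                 depth_per_mutant=1, seed=0)
        assert len(reads) == 1  # the near-end insertion cannot yield a full read

    def test_substitution_count_matches_binomial_oracle(self, small_reference):
        ref, _ = small_reference
        lib = simulate_insertion_library(ref, 100, seed=8)
        clean = synthesize_reads(lib, ref, error_rate=0.0, depth_per_mutant=2, seed=9)
        noisy = synthesize_reads(lib, ref, error_rate=0.01, depth_per_mutant=2, seed=9)
        assert len(clean) == len(noisy)
        mism = total = 0
        for (_, a, _), (_, b, _) in zip(clean, noisy):
            mism += sum(x != y for x, y in zip(a, b))
            total += len(a)
        sigma = np.sqrt(total * 0.01 * 0.99)
        assert abs(mism - total * 0.01) < 4 * sigma

    @pytest.mark.parametrize("kwargs", [{"read_length": 8}, {"error_rate": 1.0}])
    def test_bad_read_parameters_raise(self, small_reference, kwargs):
        ref, _ = small_reference
        lib = simulate_insertion_library(ref, 10, seed=0)
        with pytest.raises(ValueError):
            synthesize_reads(lib, ref, tag="CTGTCTCTTA", **kwargs)


class TestMatingAssaySimulator:
    def test_cognate_pairs_get_planted_exclusion(self):
        df = simulate_mating_assay(
            ["s1", "s2"], ["t1", "t2"], {("s1", "t1"), ("s2", "t2")},
            exclusion_fold=100.0, noise_sd_log10=0.0, seed=0,
        )
        freq = df.assign(f=df.transconjugant_cfu / df.donor_cfu)
        f_base = freq[freq.recipient == "empty"].f.mean()
        f_cog = freq[(freq.sfx_variant == "s1") & (freq.traN_variant == "t1")].f.mean()
        f_non = freq[(freq.sfx_variant == "s1") & (freq.traN_variant == "t2")].f.mean()
        assert f_base / f_cog == pytest.approx(100.0, rel=1e-6)
        assert f_base / f_non == pytest.approx(1.0, rel=1e-6)

    def test_reproducible_for_fixed_seed(self):
        a = simulate_mating_assay(["s1"], ["t1"], set(), seed=3)
        b = simulate_mating_assay(["s1"], ["t1"], set(), seed=3)
        pd.testing.assert_frame_equal(a, b)
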