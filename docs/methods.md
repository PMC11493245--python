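# Methods

## The screen model

The simulated experiment mirrors a transposon-directed insertion
sequencing (TraDIS) screen for plasmid-borne exclusion factors. A recipient
strain carrying a conjugative plasmid is saturated with mini-Tn5 insertions
(the input library) and mated with a donor transferring a mobilizable
plasmid; transconjugants form the output library. If gene *g* normally
impedes acquisition of the incoming plasmid, mutants disrupted in *g*
acquire it more often and *g* is enriched in the output.

Selection is modelled per mutant as an independent Bernoulli draw with
success probability `min(1, r · ε(g))`, where `r` is the base acquisition
probability and `ε(g)` the effect multiplier of the gene containing the
insertion (1 for intergenic positions and unlisted genes). For a gene
holding a fraction *f* of all insertions, the expected normalized
index ratio is

```
R ≈ r·ε / (r·(1 − f) + r·ε·f)
```

— for ε = 20, r = 0.01 and f ≈ 0.02 this gives ≈ 16.8, which is what the
planted-gene workflow recovers up to sampling noise and the pseudocount's
shrinkage (measured values at 10,000 mutants typically fall between 10
and 17).

## Scoring conventions

* **Insertion index.** `II_g = u_g / L_g / U`: distinct insertion sites in
  the gene (site keys are (replicon, position, strand)) per bp, divided by
  the library's total distinct sites. Unique sites rather than read counts
  are used because read counts confound insertion density with sequencing
  depth; the per-library normalization makes indices comparable between
  libraries of different size.
* **Pseudocount.** `c` defaults to half the smallest nonzero normalized
  index across both libraries. It prevents division by zero for genes with
  no input insertions while preserving the ranking of well-covered genes.
  At desk-scale output depths (~100 sites) it noticeably shrinks large
  ratios, which is why measured planted-gene ratios sit below the analytic
  expectation.
* **Threshold.** `R_g > 5` flags a candidate. The value is an arbitrary
  operating point, not a significance level, and is exposed as a flag.
* **Mapping.** Reads are tag-matched (configurable mismatch budget),
  trimmed, and placed by a unique-best exact match of their leading seed
  k-mer (default 25 bp) on either strand, with wrap-around on circular
  replicons. Seeds occurring at two or more loci are discarded as
  ambiguous; there is no mismatch-tolerant mapping. The junction
  coordinate is the first genomic base after the tag on the matched
  strand.

## Read model

Reads are single-end, `tag + junction` (default tag the first 10 bases of
the Tn5 mosaic end read-through, default read length 50), extending
3'-ward from the insertion point on the insertion's strand. The Tn5 9-bp
target-site duplication is ignored — the screen statistic only uses site
positions. Substitution errors are i.i.d. per base (tag included);
qualities are constant. Reads running off a linear replicon's end are
discarded; circular coordinates wrap modulo the length. There are no
indels, no paired ends, no PCR or coverage bias, and no growth-competition
model between platings — so passing tests demonstrate the correctness of
the scoring pipeline, not robustness to those real-data artifacts.

## Default study conditions

The canonical planted-gene experiment uses a 50-gene reference (gene
lengths uniform 300–900 bp, 100 bp spacers, 20% of genes on the plasmid
replicon), 10,000 mutants, base acquisition probability 0.01, one planted
gene with ε = 20, error-free reads at depth 10 per mutant. Library density
and depth are package choices of desk-scale convenience; they are well
below real TraDIS densities but large enough that the binomial expectations
the tests check are sharp. The neutral control runs the same conditions
with all ε = 1 over 20 seeds; under it fewer than 1% of genes cross the
ratio-5 line.

## Mating statistics

Transfer frequencies are transconjugant/donor CFU ratios; replicates with
zero transconjugants are censored at the detection limit `1/donor_cfu`
(one colony on the undiluted plate) and flagged rather than dropped, so
log-scale analyses keep them. Exclusion indices computed from censored
test frequencies carry a lower-bound flag. Frequencies are treated as
log-normal; all group statistics run on log10 values.

Bartlett and the ANOVA F/p come from scipy; the Tukey-Kramer statistic is
`q = |m_i − m_j| / sqrt((MSW/2)(1/n_i + 1/n_j))` with p-values from
scipy's studentized-range distribution (numerically integrated CDF), which
the test suite cross-checks against a 10^6-draw Monte-Carlo simulation,
the k = 2 closed form (q = √2·|t|) and statsmodels. Degenerate inputs are
defined explicitly: all-constant data give F = 0, p = 1 (and Bartlett
statistic 0); distinct means with zero within-group variance give p = 0.
The compact letter display uses the insert-and-absorb construction; it
guarantees that two groups share a letter exactly when their pairwise
p ≥ α (default 0.05, the conventional reading), without attempting a
minimal letter set.

Exclusion indices default to ratios of geometric-mean frequencies (the
natural mean on the log scale); per-replicate pairing is available via
`ei_mode="per_replicate"`.

## Exclusion groups

Matrix cells are binarized at EI ≥ 10 — one order of magnitude, chosen
because non-excluding combinations in practice sit near 1 and excluding
ones are orders of magnitude higher; twofold changes are treated as minor.
Censored lower-bound cells count as excluded when the bound clears the
cutoff. Grouping is exact profile equality after binarization: with
replicate-averaged desk-scale matrices the binary profiles are clean, so no
noisy-profile clustering is attempted. Missing cells are treated as EI = 1
with a warning. The partition is canonicalized (groups ordered by their
alphabetically first member) and is invariant to input row/column order.

## Homology

Percent identity comes from optimal global alignment with BLOSUM62,
gap open 10 / extend 0.5 (a run of L gaps costs `open + (L−1)·extend`),
X scoring 0 against everything; identity is matches over aligned columns
after discarding terminal-overhang columns. Published identities for this
protein family were derived from multiple-alignment output, which is not
bit-reproducible; recomputed pairwise identities are therefore compared at
±2 percentage points. Database searching itself is out of scope — the hit
filter (≥45% identity, ≥85% query coverage, boundaries retained) consumes
a standard tabular hit file. Greedy clustering follows the CD-HIT
convention: longest sequence first (ties by id), first-fit against cluster
representatives at ≥0.90 identity. Tree inference, alignment trimming and
signal-peptide prediction are deliberately not reimplemented.

## Numerical and design notes

* All stochastic generators accept a single seed and spawn independent
  child streams; outputs are bit-reproducible.
* GFF3 on disk is 1-based inclusive, all in-memory coordinates are 0-based
  half-open.
* The workflow entry point `simulate_and_score` can bypass read synthesis
  (`through_reads=False`) and score library site sets directly; the
  read path and the direct path agree exactly for error-free reads, which
  the round-trip tests assert.
* Known limitations: no mismatch-tolerant mapping (a single seed error
  loses the read), no essentiality analysis from input-library gaps, no
  statistical significance model for the ratio threshold, and the
  homolog-identity checks depend on externally retrieved sequences.
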