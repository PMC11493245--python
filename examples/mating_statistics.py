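"""Transfer frequencies, exclusion indices and group statistics for matings.

A miniature mating-assay data set: a mobilizable plasmid is transferred
from a donor into recipients that are empty, carry the wild-type plasmid,
or carry single/double exclusion-gene deletions. Frequencies are analyzed
on the log10 scale (Bartlett, one-way ANOVA, Tukey-Kramer, compact letter
display), and each recipient's exclusion index is the ratio of the
empty-recipient transfer frequency to its own.
"""

import numpy as np

from excluscan import compare_groups

rng = np.random.default_rng(42)

# geometric-mean transfer frequencies typical of strong exclusion (~100x)
truth = {
    "empty": 1e-3,
    "wild_type": 1e-5,       # both exclusion genes active
    "delta_sfx": 1e-4,       # surface exclusion lost
    "delta_eex": 1e-4,       # entry exclusion lost
    "delta_both": 1e-3,      # exclusion abolished
}
groups = {k: v * 10 ** rng.normal(0, 0.15, size=3) for k, v in truth.items()}

cmp = compare_groups(list(groups.values()), labels=list(groups.keys()))

print(f"Bartlett chi2 = {cmp.bartlett_stat:.3f} (p = {cmp.bartlett_p:.3f})")
print(f"one-way ANOVA F({cmp.anova_df[0]},{cmp.anova_df[1]}) = "
      f"{cmp.anova_f:.2f} (p = {cmp.anova_p:.2e})\n")

base = np.exp(np.mean(np.log(groups["empty"])))
print(f"{'recipient':<12} {'geo-mean T':>12} {'EI':>8}  letters")
for label, values in groups.items():
    gm = np.exp(np.mean(np.log(values)))
    print(f"{label:<12} {gm:>12.2e} {base / gm:>8.1f}  {cmp.letters[label]}")
print("\nEI ~ 1 means no exclusion; recipients sharing a letter are not"
      " statistically different (Tukey-Kramer on log10 frequencies).")
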