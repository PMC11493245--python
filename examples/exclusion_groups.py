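"""Infer surface-exclusion groups from an sfx x traN mating matrix.

Simulates CFU tables for donors whose conjugative plasmid carries one of
four traN adhesin variants, mated against recipients expressing one of five
sfx variants (plus an empty baseline). Cognate pairs show ~100-fold
exclusion; the inferred groups collect traN variants with identical
exclusion profiles.
"""

from excluscan import build_matrix, infer_groups, simulate_mating_assay

SFX = ["sfx_94", "sfx_Asa4c", "sfx_AhD4-1", "sfx_AQU1", "sfx_Aut1"]
TRAN = ["traN_94", "traN_Asa4c", "traN_AhD4-1", "traN_AQU1"]
COGNATE = {
    (s, t)
    for s in ("sfx_94", "sfx_Asa4c", "sfx_AhD4-1", "sfx_Aut1")
    for t in ("traN_94", "traN_Asa4c", "traN_AhD4-1")
} | {("sfx_AQU1", "traN_AQU1")}

cfu = simulate_mating_assay(SFX, TRAN, COGNATE, exclusion_fold=100.0,
                            noise_sd_log10=0.1, seed=11)
matrix = build_matrix(cfu, reference_recipient="empty")
print("exclusion-index matrix (rows: sfx in recipient, cols: traN in donor):")
print(matrix.values.round(1).to_string())

partition = infer_groups(matrix, exclusion_threshold=10.0)
print("\nsurface-exclusion groups (traN variants with identical profiles):")
for i, group in enumerate(partition.groups, 1):
    print(f"  group {i}: {', '.join(sorted(group))}")
for sfx, gids in sorted(partition.sfx_assignment.items()):
    names = ", ".join(str(g + 1) for g in sorted(gids))
    print(f"  {sfx} excludes group(s): {names}")
print("\nCells >= 10 count as exclusion; cognate cells sit near 100,"
      " non-cognate near 1.")
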