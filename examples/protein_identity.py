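"""Pairwise identities and greedy clustering of a synthetic protein family.

Builds a small synthetic family of exclusion-factor-like lipoprotein
sequences (a tight cluster of near-identical variants plus one distant
outlier), computes the all-vs-all percent-identity matrix from global
BLOSUM62 alignments, and clusters at the 0.90 identity cutoff — the
redundancy-reduction step that precedes phylogenetics.
"""

import numpy as np

from excluscan import ProteinRecord, filter_hits, greedy_cluster, identity_matrix
from excluscan.homology import HomologHit

rng = np.random.default_rng(8)
AA = "ACDEFGHIKLMNPQRSTVWY"


def mutate(seq, n):
    out = list(seq)
    for i in rng.choice(len(seq), size=n, replace=False):
        out[i] = rng.choice([c for c in AA if c != seq[i]])
    return "".join(out)


core = "".join(rng.choice(list(AA), size=200))
family = [
    ProteinRecord("Sfx_ref", core),
    ProteinRecord("Sfx_v1", mutate(core, 4)),    # ~98% identity
    ProteinRecord("Sfx_v2", mutate(core, 10)),   # ~95%
    ProteinRecord("Sfx_v3", mutate(core, 16)),   # ~92%
    ProteinRecord("Sfx_far", mutate(core, 120)), # distant outlier
]

m = identity_matrix(family)
print("pairwise percent identity:")
print(m.round(1).to_string())

clusters = greedy_cluster(family, cutoff=0.90)
print(f"\n{len(family)} proteins -> {len(clusters)} clusters at 0.90 identity:")
for rep, members in clusters.clusters:
    print(f"  representative {rep}: {', '.join(members)}")

hits = [
    HomologHit("Sfx_ref", "hit_good", pident=62.0, qcovs=0.97),
    HomologHit("Sfx_ref", "hit_low_id", pident=38.0, qcovs=0.95),
    HomologHit("Sfx_ref", "hit_low_cov", pident=70.0, qcovs=0.60),
]
kept = filter_hits(hits, min_identity=45.0, min_coverage=0.85)
print(f"\nhit filter (>=45% identity, >=85% coverage): kept "
      f"{[h.subject for h in kept]} of {[h.subject for h in hits]}")
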