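"""Ajk relatedness and family clustering on a simulated study.

Unrelated birds sit near Ajk ~ 0, half-sibs near ~0.25, first-degree
relatives (parent-offspring, full sibs) near ~0.5.  Family clusters are
connected components of the Ajk > 0.35 graph and recover one cluster
per maternal family.
"""

import numpy as np

from nestkin.genodata import filter_sites, ld_prune
from nestkin.relatedness import ajk_matrix, family_clusters
from nestkin.synthgen import SimConfig, simulate_study

sim = simulate_study(SimConfig(seed=2))
focal = sim.genotypes.subset_samples(sim.focal_ids)
filtered, _ = filter_sites(focal)
pruned = ld_prune(filtered, seed=2)

A = ajk_matrix(pruned)
truth = sim.truth.eggs
sibs, unrelated = [], []
for i, a in enumerate(A.sample_ids):
    for j in range(i + 1, len(A.sample_ids)):
        b = A.sample_ids[j]
        ra = truth[truth.sample_id == a]
        rb = truth[truth.sample_id == b]
        if len(ra) and len(rb):
            same_mom = ra.iloc[0].true_mother_id == rb.iloc[0].true_mother_id
            same_dad = ra.iloc[0].true_father_id == rb.iloc[0].true_father_id
            (sibs if same_mom and same_dad else
             unrelated if not same_mom and not same_dad else []).append(
                A.values[i, j])

print(f"{pruned.n_sites} SNPs after filtering + LD pruning")
print(f"full-sib dyads:   mean Ajk = {np.mean(sibs):.3f} (n={len(sibs)})")
print(f"unrelated dyads:  mean Ajk = {np.mean(unrelated):.3f} "
      f"(n={len(unrelated)})")

clusters = family_clusters(A, threshold=0.35)
print(f"family clusters: {len(set(clusters.values()))} "
      f"(distinct true mothers: {truth.true_mother_id.nunique()})")
# the sib mean near 0.5 and the unrelated mean near 0 are the two
# anchors the downstream dyad classification relies on.
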