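"""Jensen-Shannon divergence distances and principal coordinates analysis.

Computes the pairwise raw JSD between genus relative-abundance profiles
and ordinates by classical scaling, reporting per-axis variance shares
and any negative eigenvalues (raw JSD need not embed in Euclidean space).
"""

import numpy as np

from catgut import simulate_cohort, to_relative_abundance, jsd_matrix, pcoa

cohort = simulate_cohort(seed=1)
design = cohort.design
prop = to_relative_abundance(cohort.genus_counts)

dm = jsd_matrix(prop)
print(f"distance matrix: {len(dm.sample_ids)} samples, "
      f"max JSD = {dm.values.max():.3f} (bound ln 2 = {np.log(2):.3f})")

ordn = pcoa(dm, n_axes=2)
for k, share in enumerate(ordn.proportion_explained[:2], start=1):
    print(f"axis {k}: {share * 100:.1f}% of (positive-eigenvalue) variance")
print(f"negative eigenvalues: {(ordn.eigenvalues < -1e-12).sum()}")

for age in (18, 30, 42):
    axis1 = ordn.coordinates.loc[design.samples_at_age(age), "PCo1"]
    print(f"week {age}: mean axis-1 coordinate {axis1.mean():+.3f}")

print("\nSamples order by age along the first axis: the community is "
      "age-structured; negative eigenvalues are reported, not hidden.")
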