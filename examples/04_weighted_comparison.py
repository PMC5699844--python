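"""Cluster-normalized comparison of one descriptor between two sets.

Every cluster contributes total mass 1 (members weighted 1/cluster-size), so
an over-studied target with hundreds of near-duplicates cannot dominate the
medians, the weighted Wilcoxon rank test, or the bootstrap confidence
intervals.  The demonstration replicates one cluster 50-fold and shows that
nothing changes.
"""

import numpy as np

from allocomp.weighted_stats import (
    bootstrap_ci,
    weighted_histogram,
    weighted_median,
    weighted_wilcoxon,
)

rng = np.random.default_rng(2)

# group A: 30 singleton clusters around 0.50 aromatic fraction
vals_a = rng.normal(0.50, 0.10, 30)
# group B: 30 singleton clusters around 0.42
vals_b = rng.normal(0.42, 0.10, 30)

p = weighted_wilcoxon(vals_a, np.ones(30), vals_b, np.ones(30))
da = weighted_histogram(vals_a, np.ones(30), "a_aro/HA", 30)
db = weighted_histogram(vals_b, np.ones(30), "a_aro/HA", 30)
print(f"medians: A={weighted_median(da):.3f}  B={weighted_median(db):.3f}  p={p:.2e}")
print(f"95% CI of median A: {bootstrap_ci(da, 'median', 20000, seed=0)}")

# now blow up one observation of A into a 50-member cluster of duplicates
k = 50
vals_rep = np.concatenate([vals_a, np.full(k - 1, vals_a[0])])
clusters = np.concatenate([np.arange(30), np.zeros(k - 1, dtype=int)])
weights = np.where(clusters == 0, 1.0 / k, 1.0)
p_rep = weighted_wilcoxon(vals_rep, weights, vals_b, np.ones(30),
                          clusters, np.arange(30))
d_rep = weighted_histogram(vals_rep, weights, "a_aro/HA", 30)
print(f"after 50x duplication: median A={weighted_median(d_rep):.3f}  p={p_rep:.2e}")
print(f"|p - p_dup| = {abs(p - p_rep):.2e}")

print(
    "\nThe p-value and median are identical before and after duplication: "
    "the cluster\nweighting makes the analysis blind to how many times a "
    "compound was re-measured."
)
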