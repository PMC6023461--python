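"""Heteroscedastic statistics on position-level readouts.

Welch one-way ANOVA, Games-Howell post-hoc comparison, replicate Pearson
correlation and the replicate-equivalence rule n_a = (Var_a/Var_w) * n_w.
"""

import numpy as np

from spotscreen import (
    games_howell,
    pearson_between_replicates,
    replicates_needed,
    welch_anova,
)

rng = np.random.default_rng(3)
# spindle percentages per spot: negative control vs two knock-downs,
# with array-like spread
groups = {
    "NC": rng.normal(9.7, 2.0, 9),
    "KIF11": rng.normal(28.3, 7.4, 9),
    "PLK1": rng.normal(29.2, 7.9, 9),
}
res = welch_anova(groups)
print(f"Welch ANOVA: F={res.F:.1f}, df=({res.df1:.0f}, {res.df2:.1f}), p={res.p:.2e}")
for c in games_howell(groups):
    print(f"  {c.group1:>6} vs {c.group2:<6} diff={c.diff:+6.1f}  p={c.p:.2e}")

# how many array replicates match the standard error of 3 plate replicates?
out = replicates_needed(var_a=7.4**2, var_w=5.3**2, n_w=3)
print(f"replicate equivalence: exact {out.n_exact:.2f} -> plan for {out.n_ceiling}")
# A higher spot-to-spot variance on arrays means roughly twice as many
# array replicates are needed for the same precision.
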