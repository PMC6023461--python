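"""Quantify perinuclear EGF uptake and recover an EGFR knock-down.

Renders a negative control and a knock-down condition whose EGF-specific
intensities are scaled to 35%, measures the mean EGF signal in a
perinuclear ring around every nucleus, and reports the estimated
reduction with its Games-Howell significance.
"""

from spotscreen import train_default_model
from spotscreen.scenarios import egf_knockdown_scenario

model = train_default_model(seed=0)
res = egf_knockdown_scenario(seed=11, spots=3, replicates=2, model=model)

print(f"configured EGF reduction: {res['configured_reduction_pct']:.1f}%")
print(f"estimated EGF reduction:  {res['estimated_reduction_pct']:.1f}%")
print(f"Games-Howell p vs NC:     {res['games_howell_p']:.2e}")
# The estimate sits ~2 points below the configured truth because the
# additive cargo-channel background does not scale with the knock-down.
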