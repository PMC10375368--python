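"""DR tip speciation rates and rate variability on a simulated clade.

Computes the inverse equal-splits (DR) statistic for every tip and its
coefficient of variation — the per-clade summary used to compare rate
variability across snake radiations.
"""

from specstruct.simulate import declining_preset, simulate_bd_tree
from specstruct.tiprates import dr_statistic, rate_cv

tree = simulate_bd_tree(declining_preset(seed=5))
rates = dr_statistic(tree)
print(rates.sort_values("rate").head())
print(f"\n{tree.n_tips} tips; DR range {rates.rate.min():.3f}-{rates.rate.max():.3f}")
print(f"coefficient of variation: {rate_cv(rates):.3f}")
# DR is 1 / (pendant + internal/2 + ...): tips subtending short recent
# branches get high rates; the CV summarizes how uneven recent speciation is
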