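"""The headline question end to end: do species with stronger isolation by
distance speciate faster?

Builds a coupled synthetic world (where beta_IBD IS a monotone function of
the DR tip rate), estimates per-species beta_IBD from the genotypes, joins
them to tip rates, and runs the comparative battery.  Swap coupling to
"uncoupled" to see the null world, which mirrors the empirical finding of
decoupled rates and structure.
"""

import pandas as pd

from specstruct.comparative import decoupling_report
from specstruct.popgen import geographic_km, ibd_slope, linearize_fst, nucleotide_diversity, pairwise_fst
from specstruct.simulate import WorldParams, simulate_world

world = simulate_world(WorldParams(n_species=20, coupling="coupled", seed=8))
print(f"tree: {world.tree.n_tips} tips; {len(world.species)} species with genotype data")

rows = []
for sp in world.species:
    g = world.genotypes[sp]
    lin, _ = linearize_fst(pairwise_fst(g, min_cotyped=20))
    r = ibd_slope(lin, geographic_km(g.coords), permutations=199, seed=1, species=sp)
    rows.append({"species": sp, "beta_ibd": r.beta, "pi": nucleotide_diversity(g),
                 "n_individuals": g.n_individuals})
table = pd.DataFrame(rows)
table["tip_rate_dr"] = world.tip_rates.set_index("tip")["rate"].reindex(table.species).values

report = decoupling_report(
    table, world.tree, rate_columns=["tip_rate_dr"],
    metric_columns=["beta_ibd", "pi"], seed=1, signal_replicates=199,
)
tests = report["metric_rate_tests"]
row = tests[(tests.metric == "beta_ibd") & (tests.subset == "all")].iloc[0]
print(f"Spearman rho(beta_IBD, DR) = {row.rho:.2f}, p = {row.p:.2g}")
print(f"PGLS on retained metrics: adj r2 = "
      f"{report['pgls']['tip_rate_dr']['adj_r_squared']:.2f}, "
      f"p = {report['pgls']['tip_rate_dr']['f_pvalue']:.2g}")
# in the coupled world the correlation is strong and significant; in the
# uncoupled world it collapses to noise
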