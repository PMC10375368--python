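"""End-to-end validation experiments over the synthetic study conditions.

Each function runs one recovery/calibration experiment from scratch —
generate data, run the analysis, measure the result — and returns a dict of
measured quantities.  They are shared by the test suite and by
``scripts/acceptance.py`` so that reported numbers always come from a fresh
computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo import ltt, read_newick
from .congruence import (
    RateGrid,
    classify_trends,
    congruent_lambda,
    congruent_mu,
    fit_reference,
    make_trajectory,
    pulled_diversification_rate,
    pulled_speciation_rate,
)
from .popgen import (
    GenotypeMatrix,
    geographic_km,
    ibd_slope,
    linearize_fst,
    nucleotide_diversity,
    pairwise_fst,
)
from .simulate import (
    SimTreeParams,
    SpatialSimParams,
    WorldParams,
    declining_preset,
    simulate_bd_tree,
    simulate_bm_trait,
    simulate_spatial_genotypes,
    simulate_world,
)
from .tiprates import dr_statistic


def _seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ----------------------------------------------------------------------
# congruence-class invariant
# ----------------------------------------------------------------------
def congruence_invariant(seed: int = 0, n_draws: int = 20, slices: int = 100) -> dict:
    """Constant-rate reference (lambda=0.3, mu=0.1, T=23): random extinction
    trajectories from families 1-6 must reproduce the reference pulled
    diversification rate; identity trajectories must recover the reference."""
    t = np.linspace(0.0, 23.0, slices)
    ref = pulled_diversification_rate(
        RateGrid(times=t, lambda_=np.full(slices, 0.3), mu=np.full(slices, 0.1))
    )
    ident_l = congruent_lambda(ref, np.full(slices, 0.1))
    ident_m = congruent_mu(ref, ref.lambda_)
    max_dev = 0.0
    n_failed = 0
    n_emitted = 0
    for i, s in enumerate(_seeds(seed, n_draws)):
        model = (i % 6) + 1
        traj, _ = make_trajectory(model, 0.1, t, seed=s)
        out = congruent_lambda(ref, traj)
        if out.failed:
            n_failed += 1
            continue
        n_emitted += 1
        chk = pulled_diversification_rate(
            RateGrid(times=t, lambda_=out.lambda_, mu=traj)
        )
        max_dev = max(max_dev, float(np.max(np.abs(chk.r_p - ref.r_p))))
    return {
        "max_rp_deviation": max_dev,
        "identity_lambda_deviation": float(np.max(np.abs(ident_l.lambda_ - 0.3))),
        "identity_mu_deviation": float(np.max(np.abs(ident_m.mu - 0.1))),
        "n_emitted": n_emitted,
        "n_failed": n_failed,
    }


# ----------------------------------------------------------------------
# pulled-rate estimation oracle
# ----------------------------------------------------------------------
def constant_bd_lambda_p(times: np.ndarray, lam: float, mu: float, T: float) -> np.ndarray:
    """Closed-form pulled speciation rate lambda*(1-E) of a constant-rate
    birth-death process with complete sampling (the estimation oracle)."""
    tau = T - times
    r = lam - mu
    E = mu * (1 - np.exp(-r * tau)) / (lam - mu * np.exp(-r * tau))
    return lam * (1 - E)


def pulled_rate_oracle(
    seed: int = 0,
    n_trees: int = 100,
    lam: float = 0.3,
    mu: float = 0.1,
    min_tips: int = 200,
    grid_size: int = 100,
) -> dict:
    """Mean absolute relative error of estimated lambda_p against the
    constant-rate closed form, middle 80% of the grid."""
    errs = []
    rng = np.random.default_rng(seed)
    made = 0
    while made < n_trees:
        s = int(rng.integers(2**31 - 1))
        tree = simulate_bd_tree(
            SimTreeParams(
                lambda_fn=lambda t: lam, mu_fn=lambda t: mu, present=23.0,
                rho=1.0, min_tips=min_tips, seed=s,
            )
        )
        made += 1
        grid = pulled_speciation_rate(ltt(tree), grid_size)
        mid = slice(grid_size // 10, grid_size - grid_size // 10)
        truth = constant_bd_lambda_p(grid.times, lam, mu, tree.root_age)
        errs.append(np.mean(np.abs(grid.lambda_p[mid] - truth[mid]) / truth[mid]))
    return {"mare": float(np.mean(errs)), "n_trees": made}


def yule_lambda_p_accuracy(seed: int = 0, n_trees: int = 100, lam: float = 0.2) -> dict:
    """Mean relative deviation of the across-tree mean pulled-rate curve from
    the Yule rate (middle 80% of the grid)."""
    curves = []
    rng = np.random.default_rng(seed)
    while len(curves) < n_trees:
        s = int(rng.integers(2**31 - 1))
        tree = simulate_bd_tree(
            SimTreeParams(lambda_fn=lambda t: lam, mu_fn=lambda t: 0.0,
                          present=23.0, rho=1.0, min_tips=200, seed=s)
        )
        curves.append(pulled_speciation_rate(ltt(tree), 100).lambda_p)
    m = np.mean(curves, axis=0)[10:90]
    return {"mean_rel_dev": float(np.mean(np.abs(m - lam) / lam)), "n_trees": n_trees}


# ----------------------------------------------------------------------
# trend classification on the declining preset
# ----------------------------------------------------------------------
def declining_trend_experiment(
    seed: int = 0,
    n_replicates: int = 100,
    threshold: float = 0.02,
    mode: str = "difference",
    mu0: float = 0.05,
) -> dict:
    """Does the declining-speciation preset classify as 'decreasing'?

    Each replicate simulates a tree under the declining preset (lambda linear
    0.3 -> 0.1 over 23 My, mu 0.05, sampling 0.93), estimates lambda_p, fits
    the constant-extinction reference, and classifies per-slice trends.
    Reports the fraction of replicates whose modal category over the final
    quarter of slices is 'decreasing' (and the full category mix).
    """
    grids = []
    for s in _seeds(seed, n_replicates):
        tree = simulate_bd_tree(declining_preset(seed=s))
        pulled = pulled_speciation_rate(ltt(tree), 100)
        ref = fit_reference(pulled, mu0=mu0, rho=0.93)
        grids.append(ref)
    ts = classify_trends(grids, threshold=threshold, mode=mode)
    q = ts.categories[:, -(ts.categories.shape[1] // 4):]
    n_dec = 0
    for r in range(q.shape[0]):
        vals, counts = np.unique(q[r], return_counts=True)
        best = vals[counts == counts.max()]
        if len(best) == 1 and best[0] == -1:
            n_dec += 1
    return {
        "frac_decreasing_modal": n_dec / q.shape[0],
        "frac_slices_decreasing": float((q == -1).mean()),
        "frac_slices_flat": float((q == 0).mean()),
        "frac_slices_increasing": float((q == 1).mean()),
        "n_replicates": q.shape[0],
        "mean_lambda_root": float(np.mean([g.lambda_[0] for g in grids])),
        "mean_lambda_present": float(np.mean([g.lambda_[-1] for g in grids])),
    }


# ----------------------------------------------------------------------
# exact toy oracles
# ----------------------------------------------------------------------
def dr_toys() -> dict:
    """DR on the three hand-computable trees (2-tip, balanced 4-tip,
    caterpillar)."""
    two = dr_statistic(read_newick("(A:5,B:5);")).set_index("tip")["rate"]
    bal = dr_statistic(
        read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    ).set_index("tip")["rate"]
    cat = dr_statistic(
        read_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
    ).set_index("tip")["rate"]
    return {
        "dr_two_tip": float(two["A"]),
        "dr_balanced": float(bal["A"]),
        "dr_caterpillar": float(cat["A"]),
    }


def _toy_matrix(calls: list[list[float]]) -> GenotypeMatrix:
    arr = np.asarray(calls, dtype=float)
    n = arr.shape[0]
    coords = pd.DataFrame(
        {"individual_id": [f"i{k}" for k in range(n)], "species": "toy",
         "latitude": np.linspace(-19, -18.9, n), "longitude": np.linspace(47, 47.1, n)}
    )
    return GenotypeMatrix([f"i{k}" for k in range(n)], arr, "toy", coords)


def fst_pi_toys() -> dict:
    """Hudson Fst and unbiased pi on hand-computable matrices, with the
    brute-force per-site ratio-of-sums as the oracle."""
    fixed = pairwise_fst(_toy_matrix([[0, 0, 0, 0], [2, 2, 2, 2]]), min_cotyped=1)
    same = pairwise_fst(_toy_matrix([[0, 0], [0, 0]]), min_cotyped=1)
    g4 = _toy_matrix([[0, 2, 1, 1], [2, 2, 1, 0]])
    module_val = pairwise_fst(g4, min_cotyped=1)[0, 1]
    # independent brute force over the 4 sites
    p1 = np.array([0, 1, 0.5, 0.5])
    p2 = np.array([1, 1, 0.5, 0.0])
    num = (p1 - p2) ** 2 - p1 * (1 - p1) - p2 * (1 - p2)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    brute = num[den > 0].sum() / den[den > 0].sum()
    pi3 = nucleotide_diversity(_toy_matrix([[0, 0], [1, 0], [1, 0]]))
    return {
        "fst_fixed_pair": float(fixed[0, 1]),
        "fst_identical_pair": float(same[0, 1]),
        "fst_toy": float(module_val),
        "fst_toy_bruteforce": float(brute),
        "pi_toy": float(pi3),  # site with a=2 of m=6 gives 8/15, second site 0
    }


# ----------------------------------------------------------------------
# IBD slope recovery and Mantel calibration
# ----------------------------------------------------------------------
def ibd_recovery(
    seed: int = 0,
    beta_target: float = 0.05,
    n_seeds: int = 100,
    n_individuals: int = 20,
    n_sites: int = 5000,
    permutations: int = 0,
) -> dict:
    """Mean estimated beta_IBD over seeded replicates of the calibrated
    generator, plus (when permutations > 0) the Mantel rejection rate."""
    betas, psig = [], []
    for s in _seeds(seed, n_seeds):
        g = simulate_spatial_genotypes(
            SpatialSimParams(
                n_individuals=n_individuals, n_sites=n_sites,
                beta_target=beta_target, seed=s,
            )
        )
        lin, _ = linearize_fst(pairwise_fst(g))
        r = ibd_slope(lin, geographic_km(g.coords), permutations=permutations, seed=s)
        betas.append(r.beta)
        if permutations:
            psig.append(r.p_perm < 0.05)
    betas = np.array(betas)
    out = {
        "beta_target": beta_target,
        "mean_beta": float(betas.mean()),
        "se_beta": float(betas.std(ddof=1) / np.sqrt(len(betas))),
        "n_seeds": n_seeds,
    }
    if permutations:
        out["mantel_rejection_rate"] = float(np.mean(psig))
    return out


# ----------------------------------------------------------------------
# comparative-layer recovery
# ----------------------------------------------------------------------
def comparative_recovery(seed: int = 0, n_k: int = 200, n_lambda: int = 100) -> dict:
    """Blomberg-K calibration under BM, Pagel-lambda recovery (BM vs
    shuffled), PGLS(lambda=0) == OLS, and VIF elimination vs brute force."""
    import statsmodels.api as sm
    from itertools import combinations

    from .comparative import blomberg_k, pgls, phylosig_lambda, vif_eliminate

    rng = np.random.default_rng(seed)
    tree = simulate_bd_tree(
        SimTreeParams(lambda_fn=lambda t: 0.2, mu_fn=lambda t: 0.0,
                      present=23.0, min_tips=100, seed=int(rng.integers(2**31 - 1)))
    )
    if tree.n_tips > 120:  # ~100-tip study size; lambda profiling is O(n^3)
        tree = tree.prune_to(tree.tips[:120])
    ks = []
    for s in _seeds(seed + 1, n_k):
        x = simulate_bm_trait(tree, 1.0, 1.0, seed=s)
        ks.append(blomberg_k(tree, x, replicates=0, seed=s).estimate)
    lams_bm, lams_null = [], []
    for s in _seeds(seed + 2, n_lambda):
        x = simulate_bm_trait(tree, 1.0, 1.0, seed=s)
        lams_bm.append(phylosig_lambda(tree, x).estimate)
        shuffled = pd.Series(
            np.random.default_rng(s).permutation(x.to_numpy()), index=x.index
        )
        lams_null.append(phylosig_lambda(tree, shuffled).estimate)

    tips = tree.tips[:40]
    X = pd.DataFrame(
        {"x1": rng.normal(size=40), "x2": rng.normal(size=40)}, index=tips
    )
    y = pd.Series(2 * X.x1 - X.x2 + rng.normal(size=40), index=tips)
    sub = tree.prune_to(tips)
    fit = pgls(sub, y, X, lambda_value=0.0)
    V, order = sub.vcv(tips)
    res = sm.OLS(y.loc[order], sm.add_constant(X.loc[order])).fit()
    diffs = [
        abs(fit["coefficients"]["intercept"] - res.params["const"]),
        abs(fit["coefficients"]["x1"] - res.params["x1"]),
        abs(fit["coefficients"]["x2"] - res.params["x2"]),
    ]

    # VIF vs brute-force all-subsets on the 3-variable near-collinear case
    df = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
    df["c"] = df.a + df.b + 1e-3 * rng.normal(size=40)
    kept, _ = vif_eliminate(df, ["a", "b", "c"], threshold=10.0)

    def max_vif(cols):
        out = 0.0
        for k in cols:
            others = [c for c in cols if c != k]
            Xk = sm.add_constant(df[others])
            r2 = sm.OLS(df[k], Xk).fit().rsquared
            out = max(out, np.inf if r2 >= 1 else 1 / (1 - r2))
        return out

    best = None
    for size in (3, 2):
        for cols in combinations(["a", "b", "c"], size):
            if max_vif(list(cols)) < 10.0:
                best = set(cols)
                break
        if best:
            break
    return {
        "k_mean_bm": float(np.mean(ks)),
        "lambda_median_bm": float(np.median(lams_bm)),
        "lambda_median_shuffled": float(np.median(lams_null)),
        "pgls_ols_max_coef_diff": float(max(diffs)),
        "vif_retained": sorted(kept),
        "vif_bruteforce": sorted(best) if best else None,
        "n_k": n_k,
        "n_lambda": n_lambda,
    }


# ----------------------------------------------------------------------
# coupled / uncoupled worlds
# ----------------------------------------------------------------------
def coupling_experiment(
    seed: int = 0, coupling: str = "coupled", n_seeds: int = 100
) -> dict:
    """Fraction of synthetic worlds with a significant (p < .05) Spearman
    correlation between estimated beta_IBD and DR tip rates."""
    from scipy import stats

    sig = 0
    rhos = []
    for s in _seeds(seed, n_seeds):
        world = simulate_world(WorldParams(coupling=coupling, seed=s))
        rates = world.tip_rates.set_index("tip")["rate"]
        betas = {}
        for sp in world.species:
            g = world.genotypes[sp]
            lin, _ = linearize_fst(pairwise_fst(g, min_cotyped=20))
            r = ibd_slope(lin, geographic_km(g.coords), permutations=0, seed=0)
            betas[sp] = r.beta
        b = pd.Series(betas)
        rho, p = stats.spearmanr(b, rates.loc[b.index])
        rhos.append(rho)
        sig += p < 0.05
    return {
        "coupling": coupling,
        "frac_significant": sig / n_seeds,
        "mean_rho": float(np.mean(rhos)),
        "n_seeds": n_seeds,
    }
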