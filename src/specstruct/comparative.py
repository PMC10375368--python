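"""Correlation and phylogenetic-regression battery linking population
structure to tip speciation rates.

Joins per-species metrics (beta_IBD, pi, distance slopes, mean mtDNA
distance, mean geographic distance) to tip rates, then runs Spearman rank
correlations, phylogenetic signal (ML Pagel's lambda with a likelihood-ratio
test; Blomberg's K with permutation replicates), VIF-based multicollinearity
elimination, and PGLS with an ML lambda transform.  The headline product is
``decoupling_report``: are speciation rates and spatial population structure
associated, or decoupled?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import Phylogeny

__all__ = [
    "SignalResult",
    "spearman_matrix",
    "phylosig_lambda",
    "blomberg_k",
    "vif_eliminate",
    "pgls",
    "assemble_comparative_table",
    "decoupling_report",
]


@dataclass
class SignalResult:
    statistic: str  # "lambda" or "K"
    estimate: float
    p_value: float
    replicates: int
    degenerate: bool = False
    loglik: float | None = None
    loglik_null: float | None = None


# ----------------------------------------------------------------------
# rank correlations
# ----------------------------------------------------------------------
def spearman_matrix(
    table: pd.DataFrame, columns: list[str] | None = None, min_pairs: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rho, two-sided p, and n per cell.

    Average ranks handle ties; p uses the t approximation.  Cells with fewer
    than ``min_pairs`` complete pairs are NaN (flagged, not computed).
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(columns)
    rho = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    pval = pd.DataFrame(np.full((k, k), np.nan), index=columns, columns=columns)
    npair = pd.DataFrame(np.zeros((k, k), int), index=columns, columns=columns)
    np.fill_diagonal(pval.values, 0.0)
    for i in range(k):
        npair.iloc[i, i] = int(table[columns[i]].notna().sum())
        for j in range(i + 1, k):
            x = table[columns[i]].astype(float)
            y = table[columns[j]].astype(float)
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            npair.iloc[i, j] = npair.iloc[j, i] = n
            if n < min_pairs:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval, npair


# ----------------------------------------------------------------------
# phylogenetic signal
# ----------------------------------------------------------------------
def _lambda_cov(V: np.ndarray, lam: float) -> np.ndarray:
    d = np.diag(np.diag(V))
    return lam * V + (1 - lam) * d


def _bm_loglik(x: np.ndarray, V: np.ndarray) -> float:
    """Profile log-likelihood of a BM model with covariance sigma2*V
    (mean and sigma2 at their MLEs)."""
    n = len(x)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    one = np.ones(n)
    iv_x = np.linalg.solve(L.T, np.linalg.solve(L, x))
    iv_1 = np.linalg.solve(L.T, np.linalg.solve(L, one))
    mu = (one @ iv_x) / (one @ iv_1)
    r = x - mu
    sig2 = r @ np.linalg.solve(L.T, np.linalg.solve(L, r)) / n
    if sig2 <= 0:
        return -np.inf
    logdet = 2 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n))


def _lambda_upper(V: np.ndarray, hard_max: float = 1.1) -> float:
    """Largest lambda <= hard_max keeping V(lambda) comfortably invertible.

    The bound is a conditioning floor (smallest eigenvalue above 1e-3 of the
    mean tip variance), not the raw positive-definiteness boundary: the
    profile likelihood diverges spuriously as V(lambda) approaches
    singularity, which would park the ML estimate on the boundary with
    meaningless standard errors.
    """
    floor = 1e-3 * float(np.mean(np.diag(V)))

    def ok(lam):
        w = np.linalg.eigvalsh(_lambda_cov(V, lam))
        return w[0] > floor

    if ok(hard_max):
        return hard_max
    lo, hi = 1.0, hard_max
    if not ok(1.0):
        return 1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _align_trait(tree: Phylogeny, trait: pd.Series, min_tips: int = 10):
    trait = trait.dropna()
    labels = [t for t in tree.tips if t in trait.index]
    if len(labels) < min_tips:
        raise ValueError(f"trait covers only {len(labels)} tips; need >= {min_tips}")
    sub = tree if set(labels) == set(tree.tips) else tree.prune_to(labels)
    V, order = sub.vcv(labels)
    x = trait.loc[order].to_numpy(float)
    return x, V


def phylosig_lambda(tree: Phylogeny, trait: pd.Series, min_tips: int = 10) -> SignalResult:
    """ML Pagel's lambda with a chi-square(1) likelihood-ratio test vs lambda=0.

    lambda scales the off-diagonal (shared-path) covariances; the search runs
    on [0, lambda_max] where lambda_max (<= 1.1) keeps V(lambda) positive
    definite.  On a star tree lambda is unidentifiable and the result is
    lambda=0 with ``degenerate=True``.
    """
    x, V = _align_trait(tree, trait, min_tips)
    if np.max(np.abs(V - np.diag(np.diag(V)))) == 0:
        return SignalResult("lambda", 0.0, 1.0, 0, degenerate=True)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: lambda undefined")
    upper = _lambda_upper(V)
    obj = lambda lam: -_bm_loglik(x, _lambda_cov(V, lam))
    res = optimize.minimize_scalar(obj, bounds=(0.0, upper), method="bounded")
    cands = [(res.x, -res.fun), (0.0, _bm_loglik(x, _lambda_cov(V, 0.0))),
             (upper, _bm_loglik(x, _lambda_cov(V, upper)))]
    lam_hat, ll = max(cands, key=lambda c: c[1])
    ll0 = _bm_loglik(x, _lambda_cov(V, 0.0))
    lr = max(2 * (ll - ll0), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult("lambda", float(lam_hat), p, 0, loglik=ll, loglik_null=ll0)


def blomberg_k(
    tree: Phylogeny,
    trait: pd.Series,
    replicates: int = 999,
    seed: int | None = None,
    min_tips: int = 10,
) -> SignalResult:
    """Blomberg's K with a one-sided tip-shuffling permutation test.

    K = (MSE0/MSE) / [(tr(V) - n/(1'V^-1 1)) / (n-1)], where MSE0 is the
    mean squared deviation from the phylogenetically corrected mean and MSE
    the phylogenetically corrected mean square error; expectation 1 under
    Brownian motion.  p = (1 + #{K_perm >= K_obs}) / (1 + replicates).
    """
    x, V = _align_trait(tree, trait, min_tips)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    n = len(x)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    denom_sum = one @ Vi @ one
    expected = (np.trace(V) - n / denom_sum) / (n - 1)

    def k_of(vals: np.ndarray) -> float:
        a = (one @ Vi @ vals) / denom_sum
        r = vals - a
        mse0 = (r @ r) / (n - 1)
        mse = (r @ Vi @ r) / (n - 1)
        return float((mse0 / mse) / expected)

    k_obs = k_of(x)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(replicates):
        if k_of(rng.permutation(x)) >= k_obs:
            ge += 1
    p = (1 + ge) / (1 + replicates)
    return SignalResult("K", k_obs, float(p), replicates)


# ----------------------------------------------------------------------
# multicollinearity and PGLS
# ----------------------------------------------------------------------
def vif_eliminate(
    table: pd.DataFrame, predictors: list[str], threshold: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF predictor until all VIF < threshold.

    VIF_k = 1/(1 - R^2_k) from OLS of predictor k on the others
    (complete-case rows, intercept included); ties break by column order;
    perfect collinearity reports an infinite VIF and drops first.  Returns
    (retained predictors, per-round report).
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    retained = list(predictors)
    rows = []
    rnd = 0
    while len(retained) >= 2:
        rnd += 1
        sub = table[retained].astype(float).dropna()
        if len(sub) < len(retained) + 2:
            raise ValueError(
                f"only {len(sub)} complete rows for {len(retained)} predictors"
            )
        X = sub.to_numpy()
        vifs = []
        for k in range(X.shape[1]):
            yk = X[:, k]
            Xk = np.column_stack([np.ones(len(sub)), np.delete(X, k, axis=1)])
            beta, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
            resid = yk - Xk @ beta
            tss = np.sum((yk - yk.mean()) ** 2)
            r2 = 1 - np.sum(resid**2) / tss if tss > 0 else 0.0
            vifs.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
        for name, vf in zip(retained, vifs):
            rows.append({"round": rnd, "predictor": name, "vif": vf})
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        retained.pop(worst)
    return retained, pd.DataFrame(rows)


def pgls(
    tree: Phylogeny,
    response: pd.Series,
    predictors: pd.DataFrame,
    lambda_value: float | None = None,
) -> dict:
    """PGLS of a tip trait on species-level predictors with ML Pagel's lambda.

    Complete-case rows only (dropped rows counted); the error covariance is
    V(lambda) with lambda profiled by ML unless ``lambda_value`` fixes it.
    Returns coefficients, overall F p-value, adjusted R^2, lambda, and n.
    With lambda = 0 the fit reduces exactly to OLS.
    """
    import statsmodels.api as sm

    df = predictors.copy()
    df["__y__"] = response
    n_before = len(df)
    df = df.dropna()
    labels = [t for t in tree.tips if t in df.index]
    df = df.loc[labels]
    k = predictors.shape[1]
    if len(df) < k + 3:
        raise ValueError(f"only {len(df)} complete rows for {k} predictors")
    sub = tree if set(labels) == set(tree.tips) else tree.prune_to(labels)
    V, order = sub.vcv(labels)
    df = df.loc[order]
    y = df["__y__"].to_numpy(float)
    X = sm.add_constant(df.drop(columns="__y__").to_numpy(float))

    def neg_ll(lam: float) -> float:
        Vl = _lambda_cov(V, lam)
        try:
            L = np.linalg.cholesky(Vl)
        except np.linalg.LinAlgError:
            return np.inf
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, X)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        n = len(y)
        sig2 = (r @ r) / n
        if sig2 <= 0 or not np.isfinite(sig2):
            return np.inf
        logdet = 2 * np.sum(np.log(np.diag(L)))
        return 0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n)

    if lambda_value is None:
        upper = _lambda_upper(V)
        res = optimize.minimize_scalar(neg_ll, bounds=(0.0, upper), method="bounded")
        cands = [(res.x, -neg_ll(res.x)), (0.0, -neg_ll(0.0)), (upper, -neg_ll(upper))]
        lam_hat = float(max(cands, key=lambda c: c[1])[0])
        if not np.isfinite(neg_ll(lam_hat)):
            raise RuntimeError("lambda profile likelihood is non-finite")
    else:
        lam_hat = float(lambda_value)

    Vl = _lambda_cov(V, lam_hat)
    model = sm.GLS(y, X, sigma=Vl).fit()
    names = ["intercept"] + list(predictors.columns)
    return {
        "lambda": lam_hat,
        "coefficients": dict(zip(names, model.params)),
        "coef_se": dict(zip(names, model.bse)),
        "coef_p": dict(zip(names, model.pvalues)),
        "f_pvalue": float(model.f_pvalue),
        "r_squared": float(model.rsquared),
        "adj_r_squared": float(model.rsquared_adj),
        "n": len(y),
        "n_dropped": n_before - len(y),
        "model": model,
    }


# ----------------------------------------------------------------------
# assembly and the headline report
# ----------------------------------------------------------------------
def assemble_comparative_table(
    ibd_rows: pd.DataFrame,
    tip_rate_tables: dict[str, pd.DataFrame],
    alias_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-species metrics to tip-rate tables into one row per species.

    ``ibd_rows`` needs a ``species`` column; ``tip_rate_tables`` maps a
    column suffix (e.g. "dr") to a tip,rate table; ``alias_map`` translates
    species labels to tree tip labels (exact matching only — silent fuzzy
    matches are the classic failure mode here).  Missing cells stay missing.
    """
    tab = ibd_rows.copy()
    if alias_map:
        tab["species"] = tab["species"].map(lambda s: alias_map.get(s, s))
    tab = tab.set_index("species")
    for name, tr in tip_rate_tables.items():
        s = tr.set_index("tip")["rate"]
        tab[f"tip_rate_{name}"] = s.reindex(tab.index)
    return tab.reset_index()


def decoupling_report(
    table: pd.DataFrame,
    tree: Phylogeny,
    rate_columns: list[str],
    metric_columns: list[str],
    min_n: int = 10,
    n_column: str = "n_individuals",
    seed: int | None = None,
    signal_replicates: int = 999,
    vif_threshold: float = 10.0,
    log_rates: bool = True,
    min_signal_tips: int = 10,
) -> dict:
    """Run the full rate-vs-structure battery and return a serializable report.

    Spearman correlations between every metric and every rate column (all
    species, and restricted to species with > ``min_n`` individuals),
    phylogenetic signal (lambda, K) per rate column, VIF elimination of the
    metric set, and a PGLS of each (log) rate on the retained metrics.
    """
    missing = set(table["species"]) - set(tree.tips)
    usable = table[table["species"].isin(tree.tips)]
    if usable.empty:
        raise ValueError(
            f"no table species match tree tips; unmatched: {sorted(missing)}"
        )
    report: dict = {"n_species": len(usable), "unmatched_species": sorted(missing)}
    cols = metric_columns + rate_columns
    rho, pval, npair = spearman_matrix(usable, cols)
    report["spearman"] = {"rho": rho, "p": pval, "n": npair}
    cross = []
    for m in metric_columns:
        for r in rate_columns:
            cross.append(
                {"metric": m, "rate": r, "rho": rho.loc[m, r], "p": pval.loc[m, r],
                 "n": int(npair.loc[m, r]), "subset": "all"}
            )
    if n_column in usable:
        big = usable[usable[n_column] > min_n]
        if len(big) >= 4:
            rho2, pval2, npair2 = spearman_matrix(big, cols)
            for m in metric_columns:
                for r in rate_columns:
                    cross.append(
                        {"metric": m, "rate": r, "rho": rho2.loc[m, r],
                         "p": pval2.loc[m, r], "n": int(npair2.loc[m, r]),
                         "subset": f"n>{min_n}"}
                    )
    cross_df = pd.DataFrame(cross)
    if len(cross_df):
        # raw p-values are primary; BH-adjusted column emitted for transparency
        from statsmodels.stats.multitest import multipletests

        ok = cross_df["p"].notna()
        adj = np.full(len(cross_df), np.nan)
        if ok.sum():
            adj[ok.to_numpy()] = multipletests(cross_df.loc[ok, "p"], method="fdr_bh")[1]
        cross_df["p_bh"] = adj
    report["metric_rate_tests"] = cross_df

    rng = np.random.default_rng(seed)
    signal = {}
    indexed = usable.set_index("species")
    for r in rate_columns:
        tr = indexed[r].dropna()
        vals = np.log(tr) if log_rates else tr
        try:
            lam = phylosig_lambda(tree, vals, min_tips=min_signal_tips)
            kk = blomberg_k(
                tree, vals, replicates=signal_replicates,
                seed=int(rng.integers(2**31 - 1)), min_tips=min_signal_tips,
            )
            signal[r] = {"lambda": lam, "K": kk}
        except ValueError as e:
            signal[r] = {"error": str(e)}
    report["phylogenetic_signal"] = signal

    try:
        retained, vif_report = vif_eliminate(usable, metric_columns, vif_threshold)
    except ValueError as e:
        retained, vif_report = list(metric_columns), pd.DataFrame()
        report["vif_error"] = str(e)
    report["vif"] = {"retained": retained, "report": vif_report}

    pgls_fits = {}
    for r in rate_columns:
        resp = indexed[r]
        resp = np.log(resp) if log_rates else resp
        try:
            fit = pgls(tree, resp, indexed[retained])
            pgls_fits[r] = {k: v for k, v in fit.items() if k != "model"}
        except (ValueError, RuntimeError) as e:
            pgls_fits[r] = {"error": str(e)}
    report["pgls"] = pgls_fits
    return report
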