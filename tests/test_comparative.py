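import numpy as np
import pandas as pd
import pytest

from specstruct.comparative import (
    assemble_comparative_table,
    blomberg_k,
    decoupling_report,
    pgls,
    phylosig_lambda,
    spearman_matrix,
    vif_eliminate,
)
from specstruct.phylo import read_newick
from specstruct.simulate import simulate_bm_trait


class TestSpearmanMatrix:
    def test_monotone_transform_gives_one(self):
        t = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, 8, 27, 64, 125]})
        rho, p, n = spearman_matrix(t)
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4], "y": [9, 7, 5, 3.0]})
        rho, _, _ = spearman_matrix(t)
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_rank_computation(self):
        # d = (-1, 1, -1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        t = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        rho, _, _ = spearman_matrix(t)
        assert rho.loc["x", "y"] == pytest.approx(0.8)

    def test_few_pairs_flagged(self):
        t = pd.DataFrame({"x": [1, 2, 3, np.nan], "y": [2, 1, np.nan, 4.0]})
        rho, p, n = spearman_matrix(t, min_pairs=4)
        assert np.isnan(rho.loc["x", "y"])
        assert n.loc["x", "y"] == 2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"x": rng.uniform(size=20), "y": rng.uniform(size=20)})
        t2 = t.assign(x=np.exp(t.x * 3))
        a, _, _ = spearman_matrix(t)
        b, _, _ = spearman_matrix(t2)
        assert a.loc["x", "y"] == pytest.approx(b.loc["x", "y"])


class TestPhylosigLambda:
    def test_bm_trait_high_lambda(self, yule_tree):
        ests = [
            phylosig_lambda(yule_tree, simulate_bm_trait(yule_tree, 1.0, 1.0, seed=s)).estimate
            for s in range(15)
        ]
        assert np.median(ests) >= 0.9

    def test_shuffled_trait_low_lambda(self, yule_tree):
        rng = np.random.default_rng(1)
        ests = []
        for s in range(15):
            x = simulate_bm_trait(yule_tree, 1.0, 1.0, seed=s)
            xs = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
            ests.append(phylosig_lambda(yule_tree, xs).estimate)
        assert np.median(ests) < 0.1

    def test_star_tree_degenerate(self):
        star = read_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1,I:1,J:1);",
                           resolve_polytomies=True, seed=0)
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=10), index=star.tips)
        res = phylosig_lambda(star, x)
        assert res.degenerate
        assert res.estimate == 0.0

    def test_shift_and_scale_invariance(self, yule_tree):
        x = simulate_bm_trait(yule_tree, 1.0, 1.0, seed=3)
        a = phylosig_lambda(yule_tree, x).estimate
        b = phylosig_lambda(yule_tree, 10 * x + 7).estimate
        assert a == pytest.approx(b, abs=1e-4)

    def test_too_few_tips_errors(self, yule_tree):
        x = simulate_bm_trait(yule_tree, 1.0, 1.0, seed=4).iloc[:5]
        with pytest.raises(ValueError, match="tips"):
            phylosig_lambda(yule_tree, x)


class TestBlombergK:
    def test_bm_expectation_near_one(self, yule_tree):
        ks = [
            blomberg_k(yule_tree, simulate_bm_trait(yule_tree, 1.0, 1.0, seed=s),
                       replicates=0).estimate
            for s in range(40)
        ]
        assert 0.8 < np.mean(ks) < 1.2

    def test_shuffled_low_k_and_nonsignificant(self, yule_tree):
        rng = np.random.default_rng(5)
        x = simulate_bm_trait(yule_tree, 1.0, 1.0, seed=8)
        xs = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
        res = blomberg_k(yule_tree, xs, replicates=199, seed=6)
        assert res.estimate < 1.0
        assert res.p_value > 0.05

    def test_bm_trait_significant(self, yule_tree):
        x = simulate_bm_trait(yule_tree, 1.0, 1.0, seed=9)
        res = blomberg_k(yule_tree, x, replicates=199, seed=7)
        assert res.p_value < 0.05

    def test_constant_trait_errors(self, yule_tree):
        x = pd.Series(1.0, index=yule_tree.tips)
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(yule_tree, x, replicates=9, seed=0)

    def test_shift_scale_invariance(self, yule_tree):
        x = simulate_bm_trait(yule_tree, 1.0, 1.0, seed=10)
        a = blomberg_k(yule_tree, x, replicates=0).estimate
        b = blomberg_k(yule_tree, -3 * x + 100, replicates=0).estimate
        assert a == pytest.approx(b, rel=1e-9)


class TestVifEliminate:
    def test_orthogonal_predictors_kept(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        df = pd.DataFrame(q, columns=["a", "b", "c"])
        kept, report = vif_eliminate(df, ["a", "b", "c"])
        assert kept == ["a", "b", "c"]
        assert (report["vif"] < 1.5).all()

    def test_duplicate_column_dropped_first_round(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=20)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=20)
        kept, report = vif_eliminate(df, ["a", "b", "c"])
        # exactly one copy of the duplicated pair survives (tie broken
        # deterministically by column order: the earlier column drops)
        assert sorted(kept) == ["b", "c"]
        assert np.isinf(report.loc[report["round"] == 1, "vif"]).any()

    def test_near_collinear_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        df["c"] = df.a + df.b + 1e-3 * rng.normal(size=40)
        kept, _ = vif_eliminate(df, ["a", "b", "c"], threshold=10)
        # brute force: the largest subset with all VIF < 10 is any 2-subset;
        # deterministic tie-break drops the worst (c appears in every
        # collinear relation) leaving a and b
        assert sorted(kept) == ["a", "b"]


class TestPGLS:
    def _xy(self, tree, seed=0, n=40):
        rng = np.random.default_rng(seed)
        tips = tree.tips[:n]
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)}, index=tips)
        y = pd.Series(2 * X.x1 + rng.normal(size=n), index=tips)
        return tree.prune_to(tips), X, y

    def test_lambda_zero_equals_ols(self, yule_tree):
        import statsmodels.api as sm

        sub, X, y = self._xy(yule_tree)
        fit = pgls(sub, y, X, lambda_value=0.0)
        V, order = sub.vcv(list(X.index))
        res = sm.OLS(y.loc[order], sm.add_constant(X.loc[order])).fit()
        assert fit["coefficients"]["x1"] == pytest.approx(res.params["x1"], abs=1e-8)
        assert fit["adj_r_squared"] == pytest.approx(res.rsquared_adj, abs=1e-8)

    def test_known_effect_recovered(self, yule_tree):
        sub, X, _ = self._xy(yule_tree, seed=3)
        noise = simulate_bm_trait(sub, 0.05, 1.0, seed=4)
        y = 2 * X.x1 + noise.loc[X.index]
        fit = pgls(sub, y, X)
        assert abs(fit["coefficients"]["x1"] - 2.0) < 3 * fit["coef_se"]["x1"]

    def test_orthogonal_response_low_adj_r2(self, yule_tree):
        adj = []
        for s in range(10):
            sub, X, _ = self._xy(yule_tree, seed=20 + s)
            rng = np.random.default_rng(100 + s)
            y = pd.Series(rng.normal(size=len(X)), index=X.index)
            adj.append(pgls(sub, y, X, lambda_value=0.0)["adj_r_squared"])
        assert np.mean(adj) <= 0.05

    def test_missing_rows_dropped_and_counted(self, yule_tree):
        sub, X, y = self._xy(yule_tree)
        y2 = y.copy()
        y2.iloc[:4] = np.nan
        fit = pgls(sub, y2, X)
        assert fit["n"] == len(y) - 4
        assert fit["n_dropped"] == 4


class TestAssembleAndReport:
    def test_alias_map_exact_matching(self, caterpillar):
        ibd = pd.DataFrame({"species": ["sp.A", "B"], "beta_ibd": [0.1, 0.2]})
        tips = pd.DataFrame({"tip": list("ABCDE"), "rate": [1, 2, 3, 4, 5.0]})
        tab = assemble_comparative_table(ibd, {"dr": tips}, alias_map={"sp.A": "A"})
        assert set(tab["species"]) == {"A", "B"}
        assert tab.set_index("species").loc["A", "tip_rate_dr"] == 1

    def test_empty_intersection_errors(self, caterpillar):
        tab = pd.DataFrame({"species": ["X", "Y"], "m": [1.0, 2.0],
                            "r": [0.1, 0.2]})
        with pytest.raises(ValueError, match="unmatched"):
            decoupling_report(tab, caterpillar, ["r"], ["m"])

    def test_report_smoke(self, yule_tree):
        rng = np.random.default_rng(0)
        species = yule_tree.tips[:20]
        tab = pd.DataFrame(
            {"species": species,
             "beta_ibd": rng.uniform(0.01, 0.1, 20),
             "pi": rng.uniform(0.1, 0.3, 20),
             "n_individuals": rng.integers(3, 20, 20),
             "tip_rate_dr": rng.uniform(0.1, 0.5, 20)}
        )
        rep = decoupling_report(
            tab, yule_tree, ["tip_rate_dr"], ["beta_ibd", "pi"],
            seed=1, signal_replicates=49, min_signal_tips=10,
        )
        assert rep["n_species"] == 20
        assert {"metric_rate_tests", "phylogenetic_signal", "vif", "pgls"} <= set(rep)
        assert "p_bh" in rep["metric_rate_tests"].columns
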