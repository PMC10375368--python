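import numpy as np
import pytest

from specstruct.congruence import (
    MODEL_IDS,
    RateGrid,
    classify_trends,
    congruent_lambda,
    congruent_mu,
    fit_reference,
    make_trajectory,
    pulled_diversification_rate,
    pulled_speciation_rate,
    rp_from_lambda_p,
)
from specstruct.phylo import ltt, read_newick
from specstruct.simulate import SimTreeParams, simulate_bd_tree


def const_ref(lam=0.3, mu=0.1, T=23.0, n=100):
    t = np.linspace(0.0, T, n)
    return pulled_diversification_rate(
        RateGrid(times=t, lambda_=np.full(n, lam), mu=np.full(n, mu))
    )


class TestPulledDiversificationRate:
    def test_constant_rates(self):
        ref = const_ref()
        assert np.allclose(ref.r_p, 0.2, atol=1e-9)

    def test_exponential_lambda_analytic(self):
        # lambda(t) = l0 e^{kt}: d lambda/dtau = -k lambda, so r_p = lambda - k
        t = np.linspace(0, 10, 1000)
        lam = 0.1 * np.exp(0.05 * t)
        g = pulled_diversification_rate(RateGrid(times=t, lambda_=lam, mu=np.zeros(1000)))
        assert np.max(np.abs(g.r_p - (lam - 0.05))) < 1e-3

    def test_grid_doubling_does_not_worsen_error(self):
        # log-space differencing is exact for the exponential, so the check
        # uses a non-loglinear trajectory to see the h^2 trend
        errs = []
        for n in (500, 1000):
            t = np.linspace(0, 10, n)
            lam = 0.2 + 0.1 * np.sin(t)
            g = pulled_diversification_rate(
                RateGrid(times=t, lambda_=lam, mu=np.zeros(n))
            )
            truth = lam + 0.1 * np.cos(t)  # -d lambda/dt enters with minus: lam - mu - lam'/lam...
            truth = lam - 0.0 - (0.1 * np.cos(t)) / lam
            errs.append(np.max(np.abs(g.r_p - truth)))
        assert errs[1] <= errs[0] / 2 + 1e-12

    def test_zero_lambda_errors(self):
        t = np.linspace(0, 1, 10)
        g = RateGrid(times=t, lambda_=np.zeros(10), mu=np.zeros(10))
        with pytest.raises(ValueError, match="positive"):
            pulled_diversification_rate(g)

    def test_consistency_with_pulled_speciation_identity(self):
        # for constant-rate BD with rho=1 the two r_p routes agree
        ref = const_ref()
        tau = ref.times[-1] - ref.times
        r = 0.3 - 0.1
        E = 0.1 * (1 - np.exp(-r * tau)) / (0.3 - 0.1 * np.exp(-r * tau))
        lam_p = 0.3 * (1 - E)
        g = rp_from_lambda_p(RateGrid(times=ref.times, lambda_p=lam_p))
        mid = slice(2, -2)
        assert np.max(np.abs(g.r_p[mid] - 0.2)) < 1e-4


class TestCongruenceMap:
    def test_identity_members_recovered(self):
        ref = const_ref()
        out = congruent_lambda(ref, np.full(100, 0.1))
        assert not out.failed
        assert np.max(np.abs(out.lambda_ - 0.3)) < 1e-6
        back = congruent_mu(ref, ref.lambda_)
        assert np.max(np.abs(back.mu - 0.1)) < 1e-6

    @pytest.mark.parametrize("model", [1, 2, 3, 4, 5, 6])
    def test_emitted_members_reproduce_rp(self, model):
        """The module's defining invariant: congruent pairs share r_p."""
        ref = const_ref()
        t = ref.times
        n_emitted = 0
        for s in range(8):
            traj, target = make_trajectory(model, 0.1, t, seed=100 * model + s)
            out = congruent_lambda(ref, traj)
            if out.failed:
                continue
            n_emitted += 1
            chk = pulled_diversification_rate(
                RateGrid(times=t, lambda_=out.lambda_, mu=traj)
            )
            assert np.max(np.abs(chk.r_p - ref.r_p)) < 1e-3
        assert n_emitted > 0

    def test_round_trip_mu_recovery_smooth(self):
        ref = const_ref()
        traj, _ = make_trajectory(4, 0.1, ref.times, seed=5)
        out = congruent_lambda(ref, traj)
        rt = congruent_mu(ref, out.lambda_)
        assert np.nanmax(np.abs(rt.mu - traj)) < 1e-3

    def test_episodic_member_valid_away_from_shift(self):
        ref = const_ref()
        traj, _ = make_trajectory(11, 0.1, ref.times, seed=3)
        out = congruent_lambda(ref, traj, rp_tol=1e-2)
        assert not out.failed
        chk = pulled_diversification_rate(
            RateGrid(times=ref.times, lambda_=out.lambda_, mu=np.clip(traj, 0, 1))
        )
        dmu = np.abs(np.diff(traj))
        mask = np.ones(100, bool)
        for j in np.flatnonzero(dmu > 0.01):
            mask[max(j - 2, 0) : j + 4] = False
        assert np.max(np.abs(chk.r_p[mask] - ref.r_p[mask])) < 1e-2

    def test_low_speciation_high_extinction_fails_not_raises(self):
        t = np.linspace(0, 23, 100)
        ref = pulled_diversification_rate(
            RateGrid(times=t, lambda_=np.full(100, 0.09), mu=np.full(100, 0.05))
        )
        out = congruent_lambda(ref, np.full(100, 1.0))
        assert out.failed

    def test_negative_mu_flagged(self):
        ref = const_ref()
        lam_star = np.full(100, 0.05)  # below r_p: mu* must go negative
        out = congruent_mu(ref, lam_star)
        assert out.negative_mu_slices == 100
        assert np.all(out.mu < 0)


class TestTrajectories:
    def test_linear_twofold_increase_exact(self):
        t = np.linspace(0, 23, 100)
        traj, target = make_trajectory(2, 0.2, t, seed=1)
        assert target == "mu"
        assert traj[0] == pytest.approx(0.2)
        assert traj[-1] == pytest.approx(0.4)
        assert np.allclose(np.diff(traj, 2), 0, atol=1e-12)  # exactly linear

    def test_seed_determinism_and_fold_calibration(self):
        t = np.linspace(0, 23, 100)
        a, _ = make_trajectory(1, 0.1, t, seed=9)
        b, _ = make_trajectory(1, 0.1, t, seed=9)
        assert np.array_equal(a, b)
        folds = []
        for s in range(100):
            tr, _ = make_trajectory(1, 0.1, t, seed=s)
            folds.append(tr.max() / tr.min())
        assert np.mean(np.array(folds) <= 2.0) >= 0.95

    def test_episodic_single_shift(self):
        t = np.linspace(0, 23, 100)
        traj, _ = make_trajectory(11, 0.2, t, seed=4)
        # strip the lognormal slice noise by comparing medians of the two
        # regimes: they must differ twofold
        d = np.abs(np.diff(np.log(traj)))
        shift = np.argmax(d)
        pre, post = np.median(traj[: shift + 1]), np.median(traj[shift + 1 :])
        assert max(pre, post) / min(pre, post) == pytest.approx(2.0, rel=0.2)

    def test_speciation_models_capped(self):
        t = np.linspace(0, 23, 100)
        traj, target = make_trajectory(8, 0.4, t, seed=2)
        assert target == "lambda"
        assert traj.max() <= 0.5 + 1e-12

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError, match="valid ids"):
            make_trajectory(12, 0.1, np.linspace(0, 1, 10), seed=0)


class TestPulledSpeciationRate:
    def test_two_lineage_flat_ltt_gives_zero(self):
        curve = ltt(read_newick("(A:5,B:5);"))
        # a flat log-LTT has zero derivative everywhere; too few events for a
        # spline fit is the documented error
        with pytest.raises(ValueError, match="smaller smoothing_df"):
            pulled_speciation_rate(curve, 50, 6)

    def test_yule_slope_recovery_single_large_tree(self):
        tree = simulate_bd_tree(
            SimTreeParams(lambda_fn=lambda t: 0.25, mu_fn=lambda t: 0.0,
                          present=23.0, min_tips=250, seed=11)
        )
        g = pulled_speciation_rate(ltt(tree), 100)
        mid = slice(20, 90)
        rel = np.abs(g.lambda_p[mid] - 0.25) / 0.25
        assert np.mean(rel) < 0.25

    def test_negative_clips_counted(self):
        tree = simulate_bd_tree(
            SimTreeParams(lambda_fn=lambda t: 0.3, mu_fn=lambda t: 0.2,
                          present=15.0, min_tips=20, seed=5)
        )
        g = pulled_speciation_rate(ltt(tree), 100)
        assert (g.lambda_p >= 0).all()
        assert g.negative_lambda_p_clips >= 0


class TestClassifyTrends:
    def _grid(self, lam):
        t = np.linspace(0, 23, len(lam))
        return RateGrid(times=t, lambda_=np.asarray(lam, float))

    def test_constant_lambda_all_flat(self):
        grids = [self._grid(np.full(50, 0.3)) for _ in range(5)]
        ts = classify_trends(grids, threshold=0.02)
        assert (ts.categories == 0).all()
        assert np.allclose(ts.frequencies["flat"], 1.0)
        assert (ts.modal == 0).all()

    def test_single_step_detected(self):
        lam = np.full(50, 0.3)
        lam[25:] += 0.05
        ts = classify_trends([self._grid(lam)], threshold=0.02)
        assert (ts.categories == 1).sum() == 1
        assert ts.categories[0, 24] == 1

    def test_failed_replicates_excluded_and_counted(self):
        good = self._grid(np.full(50, 0.3))
        bad = self._grid(np.full(50, 0.3))
        bad.failed = True
        ts = classify_trends([good, bad], threshold=0.02)
        assert ts.n_replicates == 1
        assert ts.n_failed == 1

    def test_mismatched_grids_error(self):
        a = self._grid(np.full(50, 0.3))
        b = RateGrid(times=np.linspace(0, 10, 50), lambda_=np.full(50, 0.3))
        with pytest.raises(ValueError, match="share"):
            classify_trends([a, b])

    def test_tie_breaks_to_flat(self):
        up = np.full(50, 0.3)
        up[25:] += 0.05
        down = np.full(50, 0.3)
        down[25:] -= 0.05
        ts = classify_trends([self._grid(up), self._grid(down)], threshold=0.02)
        assert ts.modal[24] == 0


class TestFitReference:
    def test_constant_rate_recovery(self):
        # lambda_p of a constant-rate complete-sampling BD: the fitted
        # constant-mu reference should recover lambda
        t = np.linspace(0, 23, 100)
        tau = t[-1] - t
        r = 0.3 - 0.1
        E = 0.1 * (1 - np.exp(-r * tau)) / (0.3 - 0.1 * np.exp(-r * tau))
        pulled = RateGrid(times=t, lambda_p=0.3 * (1 - E))
        ref = fit_reference(pulled, mu0=0.1, rho=1.0)
        mid = slice(5, -5)
        assert np.max(np.abs(ref.lambda_[mid] - 0.3)) < 0.02
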