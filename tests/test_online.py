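"""Online-adaptation contracts: EWMA baselines, CUSUM detection, the SPRT
variant, sketched gradients and the detect-then-update loop."""

import numpy as np
import pytest
from scipy import stats

from agile_har import online


class TestEwma:
    def test_constant_input_fixed_point(self):
        st = online.CusumState(d=2)
        st.mean = np.array([3.0, -1.0])
        st.var = np.array([0.5, 0.5])
        for _ in range(200):
            online.ewma_update(st, np.array([3.0, -1.0]))
        np.testing.assert_allclose(st.mean, [3.0, -1.0])
        np.testing.assert_allclose(st.var, online.VAR_FLOOR, atol=1e-10)

    def test_alpha_one_tracks_exactly(self):
        st = online.CusumState(d=1, alpha_ewma=1 - 1e-12)
        online.ewma_update(st, np.array([7.0]))
        assert st.mean[0] == pytest.approx(7.0)

    def test_long_run_variance(self):
        rng = np.random.default_rng(0)
        st = online.CusumState(d=1)
        vals = []
        for t in range(10_000):
            online.ewma_update(st, rng.normal(0, 1, 1))
            if t > 5000:
                vals.append(st.var[0])
        assert np.mean(vals) == pytest.approx(1.0, rel=0.15)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            online.CusumState(d=1, alpha_ewma=1.5)


class TestCusum:
    def test_warmup_never_alarms(self):
        st = online.CusumState(d=3, warmup=30)
        rng = np.random.default_rng(1)
        for _ in range(29):
            st, alarms = online.cusum_step(st, rng.normal(5, 0.1, 3))
            assert alarms == []

    def test_on_baseline_statistic_stays_zero(self):
        st = online.CusumState(d=2, kappa=1.0)
        for _ in range(200):
            st, _ = online.cusum_step(st, np.array([2.0, -3.0]))
        # constant stream equals the frozen baseline: negative drift, max(0,.)
        np.testing.assert_allclose(st.S, 0.0)

    def test_bonferroni_quantile(self):
        st = online.CusumState(d=5, alpha_err=0.005)
        assert st.quantile == pytest.approx(3.2905, abs=1e-4)

    def test_few_false_alarms_when_stationary(self):
        total = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            st = online.CusumState(d=5)
            for _ in range(5000):
                st, alarms = online.cusum_step(st, rng.normal(0, 1, 5))
                total += len(alarms)
        assert total <= 3

    def test_shift_always_detected(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            st = online.CusumState(d=4)
            hit = False
            for t in range(700):
                x = rng.normal(0, 1, 4)
                if t >= 200:
                    x[1] += 2.0
                st, alarms = online.cusum_step(st, x)
                if alarms and t >= 200:
                    assert 1 in alarms[0].dims
                    hit = True
                    break
            assert hit, f"seed {seed}: shift missed"

    def test_alarm_resets_statistic(self):
        rng = np.random.default_rng(2)
        st = online.CusumState(d=2)
        for t in range(400):
            x = rng.normal(0, 1, 2)
            if t >= 100:
                x[0] += 3.0
            st, alarms = online.cusum_step(st, x)
            if alarms:
                assert st.S[list(alarms[0].dims)].max() == 0.0
                for d_idx in alarms[0].dims:
                    assert alarms[0].S_at_alarm[d_idx] >= alarms[0].h_at_alarm[d_idx]
                break
        else:
            pytest.fail("no alarm raised")

    def test_wrong_dimension_rejected(self):
        st = online.CusumState(d=3)
        with pytest.raises(ValueError):
            online.cusum_step(st, np.zeros(4))


class TestSprt:
    def test_identical_densities_stay_zero(self):
        p = stats.norm(0, 1).pdf
        S = 0.0
        for y in np.linspace(-2, 2, 50):
            S, alarm = online.sprt_step(S, y, p, p, h=5.0)
            assert S == 0.0 and not alarm

    def test_kl_drift_rate(self):
        # increments under p1 average KL(p1 || p0) = 0.5 for unit-shift Gaussians
        rng = np.random.default_rng(7)
        p0, p1 = stats.norm(0, 1).pdf, stats.norm(1, 1).pdf
        S, n = 0.0, 10_000
        for y in rng.normal(1, 1, n):
            S, _ = online.sprt_step(S, y, p0, p1, h=np.inf)
        assert S / n == pytest.approx(0.5, rel=0.10)

    def test_zero_threshold_alarms_on_positive_increment(self):
        p0, p1 = stats.norm(0, 1).pdf, stats.norm(1, 1).pdf
        S, alarm = online.sprt_step(0.0, 2.0, p0, p1, h=0.0)
        assert alarm and S > 0

    def test_zero_density_clipped(self):
        S, _ = online.sprt_step(0.0, 0.0, lambda y: 0.0, lambda y: 1.0, h=np.inf)
        assert S == 50.0


class TestSketchGradient:
    def test_orthogonal_projection_identity(self, rng):
        d = 6
        Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        P = np.sqrt(d) * Q.T  # P^T P = d I
        G = rng.normal(size=(4, d))
        np.testing.assert_allclose(online.sketch_gradient(G, P, d), G, atol=1e-10)

    def test_zero_gradient(self, rng):
        P = rng.normal(size=(3, 8))
        assert np.all(online.sketch_gradient(np.zeros((2, 8)), P, 3) == 0)

    def test_jl_norm_concentration(self):
        # the r-dimensional compression G P^T / sqrt(r) with r = 4 ln d keeps
        # the norm within +-50% for >= 95% of random gradients (JL lemma);
        # the reconstruction (1/r) G P^T P is unbiased for G but carries an
        # extra factor ~sqrt(1 + d/r) in norm, so the concentration statement
        # is about the compressed representation
        d = 100
        r = int(np.ceil(4 * np.log(d)))
        rng = np.random.default_rng(11)
        ok = 0
        n_trials = 1000
        for _ in range(n_trials):
            G = rng.normal(size=(5, d))
            P = rng.normal(size=(r, d))
            ratio = np.linalg.norm(G @ P.T / np.sqrt(r)) / np.linalg.norm(G)
            ok += 0.5 <= ratio <= 1.5
        assert ok / n_trials >= 0.95

    def test_reconstruction_unbiased(self):
        # averaging the sketch-reconstruct operator over many projections
        # recovers the gradient (E[(1/r) P^T P] = I)
        rng = np.random.default_rng(4)
        G = rng.normal(size=(3, 12))
        acc = np.zeros_like(G)
        n = 4000
        for _ in range(n):
            P = rng.normal(size=(6, 12))
            acc += online.sketch_gradient(G, P, 6)
        np.testing.assert_allclose(acc / n, G, atol=0.15)

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            online.sketch_gradient(np.ones((2, 3)), np.ones((1, 3)), r=0)


class TestAcgd:
    def _quadratic(self, seed=0, d=10, n=200):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        W_star = rng.normal(size=(d, 3))
        Y = X @ W_star
        return X, Y, W_star

    def test_fixed_point_at_optimum(self):
        X, Y, W_star = self._quadratic()
        cfg = online.AcgdConfig(r=10, ridge=0.0, max_iter=20, eta_learn=0.01,
                                update_budget_ms=1e6)
        out = online.acgd_update(W_star.copy(), X, Y, cfg)
        np.testing.assert_allclose(out, W_star, atol=1e-8)

    def test_linear_convergence_on_quadratic(self):
        # in the exact-sketch limit (P^T P = r I) the iteration is gradient
        # descent and every squared error ratio obeys 1 - mu/(L (1+eps)^2)
        # with the measured distortion eps = 0
        X, Y, W_star = self._quadratic(seed=1)
        H = 2 * X.T @ X / len(X)
        eigs = np.linalg.eigvalsh(H)
        mu, L = eigs[0], eigs[-1]
        d = 10
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        P = np.sqrt(d) * Q.T
        eta = 1 / L
        W = np.zeros_like(W_star)
        errs, eps_max = [np.linalg.norm(W - W_star)], 0.0
        for _ in range(50):
            G = 2 * X.T @ (X @ W - Y) / len(X)
            g = online.sketch_gradient(G.T, P, d).T
            eps_max = max(eps_max, np.linalg.norm(g - G) / np.linalg.norm(G))
            W = W - eta * g
            errs.append(np.linalg.norm(W - W_star))
        errs = np.array(errs)
        assert eps_max < 1e-8
        bound = 1 - mu / (L * (1 + eps_max) ** 2)
        ratios = (errs[1:] / errs[:-1]) ** 2
        assert np.all(ratios <= bound + 1e-9)
        assert errs[-1] < 0.1 * errs[0]  # visibly linear convergence

    def test_gaussian_sketch_still_converges(self):
        # with a fixed Gaussian projection the conditioned iteration remains
        # a contraction: error decreases monotonically toward the optimum
        X, Y, W_star = self._quadratic(seed=2)
        L = np.linalg.eigvalsh(2 * X.T @ X / len(X))[-1]
        cfg = online.AcgdConfig(r=10, ridge=0.0, max_iter=300,
                                eta_learn=0.3 / L, seed=3, update_budget_ms=1e6,
                                grad_tol=0.0)
        W = np.zeros_like(W_star)
        e0 = np.linalg.norm(W - W_star)
        out = online.acgd_update(W, X, Y, cfg)
        assert np.linalg.norm(out - W_star) < 0.2 * e0

    def test_zero_budget_returns_unchanged(self):
        X, Y, W_star = self._quadratic()
        cfg = online.AcgdConfig(update_budget_ms=0.0)
        W0 = np.ones_like(W_star)
        assert online.acgd_update(W0, X, Y, cfg) is W0

    def test_default_step_size(self):
        assert online.AcgdConfig().eta_learn == pytest.approx(0.001)

    def test_default_projection_dim(self):
        assert online.AcgdConfig().resolve_r(256) == int(np.ceil(4 * np.log(256)))
        assert online.AcgdConfig().resolve_r(2) == 2


class TestMonitorLoop:
    def _drifting_stream(self, seed, n=2000, t0=1000, d=4):
        rng = np.random.default_rng(seed)
        F = rng.normal(0, 1, (n, d))
        F[t0:, 0] += 2.0
        y = (F[:, 1] > 0).astype(int)
        return F, y

    def test_stationary_stream_no_updates(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(5000, 4))
        y = rng.integers(0, 2, 5000)
        W = rng.normal(size=(4, 2))
        res = online.monitor_update_loop(F, y, W, n_classes=2)
        assert res.n_updates <= 1  # event triggering respects the error rate

    def test_drift_triggers_update_and_reset(self):
        for seed in range(10):
            F, y = self._drifting_stream(seed)
            W = np.zeros((4, 2))
            res = online.monitor_update_loop(F, y, W, n_classes=2)
            ts = [a.t for a in res.alarms if a.t >= 1000]
            assert ts and ts[0] <= 1500
            assert res.n_updates >= 1
            assert not np.array_equal(res.model, W)

    def test_label_starvation_skips_update(self):
        F, y = self._drifting_stream(0, n=300, t0=50)
        # labels delayed beyond the alarm: no supervision available yet
        res = online.monitor_update_loop(
            F, y, np.zeros((4, 2)), label_delay=280, n_classes=2
        )
        assert res.starvations >= 1
        assert res.n_updates == 0
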