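"""Selection-strategy contracts: KDE mutual information, submodular greedy
with lazy evaluation, heuristic gating, competitive dynamics and MCTS
candidate generation."""

import numpy as np
import pytest
from sklearn.feature_selection import mutual_info_classif

from agile_har import activation as act


def _table(scores, grads=None):
    scores = np.asarray(scores, float)
    g = np.zeros_like(scores) if grads is None else np.asarray(grads, float)
    return act.ImportanceTable(s=scores, mi=np.clip(scores, 0, None), grad=g)


class TestMiKde:
    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000)
        assert act.mi_kde(f, y) < 0.05

    def test_binary_label_one_bit(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 5000)
        f = y + rng.normal(0, 0.05, 5000)
        assert act.mi_kde(f, y) == pytest.approx(np.log(2), rel=0.10)

    def test_constant_feature_zero(self):
        y = np.array([0, 1] * 20)
        assert act.mi_kde(np.full(40, 3.3), y) == 0.0

    def test_agrees_with_knn_estimator(self):
        # independent cross-check against the Kraskov estimator on a
        # moderately informative feature
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 4000)
        f = 0.8 * y + rng.normal(0, 1.0, 4000)
        ours = act.mi_kde(f, y)
        theirs = mutual_info_classif(
            f.reshape(-1, 1), y, n_neighbors=5, random_state=0
        )[0]
        assert ours == pytest.approx(theirs, rel=0.2, abs=0.03)

    def test_bandwidth_override(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 1000)
        f = y + rng.normal(0, 0.1, 1000)
        wide = act.mi_kde(f, y, bandwidth=2.0)  # oversmoothing washes out MI
        assert wide < act.mi_kde(f, y)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            act.mi_kde(np.ones(10), np.zeros(10))
        with pytest.raises(ValueError):
            act.mi_kde(np.random.default_rng(0).normal(size=30), np.zeros(30))


class TestConditionalGain:
    def test_empty_set_reduces_to_mi(self):
        t = _table([0.5, 0.2])
        assert act.conditional_gain(0, [], t) == pytest.approx(0.5)

    def test_duplicate_feature_near_zero_gain(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 1500)
        f = (y + rng.normal(0, 0.3, 1500)).reshape(-1, 1)
        features = np.hstack([f, f])  # unit 1 duplicates unit 0
        mi0 = act.mi_kde(features[:, 0], y)
        t = act.ImportanceTable(
            s=np.array([mi0, mi0]), mi=np.array([mi0, mi0]), grad=np.zeros(2)
        )
        assert act.conditional_gain(1, [0], t, features, y) <= 0.05

    def test_diminishing_returns_in_selected_set(self):
        # the redundancy penalty grows (weakly) with the selected set, so the
        # marginal gain w.r.t. S is >= the gain w.r.t. any superset S'
        rng = np.random.default_rng(5)
        features = rng.normal(size=(400, 6))
        y = rng.integers(0, 2, 400)
        mi = np.array([act.mi_kde(features[:, j], y) for j in range(6)])
        t = act.ImportanceTable(s=mi, mi=mi, grad=np.zeros(6))
        for _ in range(50):
            j = int(rng.integers(6))
            others = [k for k in range(6) if k != j]
            rng.shuffle(others)
            cut = int(rng.integers(1, 5))
            S, S_sup = others[:cut], others[: cut + 1]
            g_small = act.conditional_gain(j, S, t, features, y)
            g_large = act.conditional_gain(j, S_sup, t, features, y)
            assert g_small >= g_large - 1e-12


class TestGreedy:
    def test_modular_utility_picks_top_k(self):
        t = _table([0.9, 0.1, 0.8, 0.3, 0.7, 0.2, 0.05, 0.6])
        mask = act.greedy_select(t, K=3)  # no features: zero redundancy
        assert set(mask.active) == {0, 2, 4}

    def test_budget_exceeding_units_activates_all(self):
        t = _table([0.5, 0.4])
        with pytest.warns(UserWarning):
            mask = act.greedy_select(t, K=5)
        assert mask.a.sum() == 2

    def test_coverage_guarantee_small(self):
        # greedy utility >= (1 - 1/e) * optimum on weighted-coverage instances
        from itertools import combinations

        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, K = 10, 3
            cover = [
                frozenset(rng.choice(15, size=rng.integers(1, 6), replace=False))
                for _ in range(n)
            ]
            w = rng.integers(1, 1000, 15).astype(float)

            def util(S):
                covered = set().union(*(cover[j] for j in S)) if S else set()
                return w[sorted(covered)].sum()

            def gain(j, sel):
                return util(list(sel) + [j]) - util(sel)

            sel = act.lazy_greedy_maximize(gain, np.arange(n), K)
            opt = max(util(list(c)) for c in combinations(range(n), K))
            assert util(sel) >= (1 - 1 / np.e) * opt - 1e-12

    def test_lazy_matches_naive(self):
        def naive(gain_fn, cands, K):
            sel, pool = [], list(cands)
            while len(sel) < K and pool:
                g, j = max((gain_fn(j, sel), -j) for j in pool)
                j = -j
                if g <= 0 and sel:
                    break
                sel.append(j)
                pool.remove(j)
            return sel

        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 12
            cover = [
                frozenset(rng.choice(20, size=rng.integers(1, 6), replace=False))
                for _ in range(n)
            ]
            w = rng.integers(1, 1000, 20).astype(float)

            def gain(j, sel):
                cur = set().union(*(cover[i] for i in sel)) if sel else set()
                return w[sorted(cover[j] - cur)].sum()

            assert act.lazy_greedy_maximize(gain, np.arange(n), 4) == naive(
                gain, np.arange(n), 4
            )

    def test_k_default_is_five(self):
        from agile_har.pipeline import PipelineConfig

        assert PipelineConfig().K == 5


class TestHgf:
    def test_threshold_endpoint(self):
        p = act.GatingParams(tau0=1.0, tau_min=0.05, beta=3.5)
        t = _table(np.linspace(0, 1, 8))
        mask = act.hgf_gate(t, p, T_used=p.T_max, K=4)
        tau_end = max(p.tau0 * np.exp(-p.beta), p.tau_min)
        expect = (t.s >= tau_end).sum()
        assert mask.a.sum() == min(max(expect, 1), 4)

    def test_safety_floor_single_unit(self):
        p = act.GatingParams(tau0=1.0, tau_min=0.9, gamma=0.0)
        t = _table([0.1, 0.3, 0.2])
        mask = act.hgf_gate(t, p, T_used=0.0, K=3)
        assert mask.a.sum() == 1 and mask.active[0] == 1  # best score wins

    def test_uniform_scores_trimmed_by_margin(self):
        # all units pass the raw gate; enforcement must keep exactly the K
        # with the largest margins s_j - (tau - gamma * grad_j)
        p = act.GatingParams(tau0=0.5, tau_min=0.05, gamma=0.1)
        grads = np.array([0.9, 0.1, 0.5, 0.7, 0.3, 0.8])
        t = _table(np.full(6, 0.5), grads=grads)
        K = 3
        mask = act.hgf_gate(t, p, T_used=0.0, K=K)
        # oracle: simulate the enforcement directly
        tau = max(p.tau0, p.tau_min)
        margin = t.s - (tau - p.gamma * grads)
        keep = np.argsort(-margin, kind="stable")[:K]
        assert set(mask.active) == set(keep)
        assert mask.a.sum() == K

    def test_beta_bound_enforced(self):
        with pytest.raises(ValueError, match="beta"):
            act.GatingParams(tau0=1.0, tau_min=0.05, beta=0.5)


class TestDwalcnn:
    def test_decoupled_limit_ranks_by_sigmoid(self):
        # mu = 0: fixed points a* = sigma(s - tau)/lam are strictly ordered by
        # score whenever they stay interior
        s = np.array([0.05, 0.35, 0.2, 0.1, 0.3]) - 0.6  # all below tau
        t = _table(s + 0.6)
        state = act.CompetitionState(n_units=5, tau=0.6)
        mask, _ = act.dwalcnn_select(t, state, K=2)
        assert set(mask.active) == {1, 4}  # the two largest scores

    def test_lyapunov_nonincreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 16))
            mu = rng.uniform(0, 0.5, (n, n))
            mu = (mu + mu.T) / 2
            np.fill_diagonal(mu, 0)
            t = _table(rng.uniform(0, 1, n))
            state = act.CompetitionState(n_units=n, mu=mu)
            _, _, energies = act.dwalcnn_select(t, state, K=3, record_energy=True)
            assert np.all(np.diff(energies) <= 1e-9)

    def test_hebbian_coefficients_stay_bounded(self):
        rng = np.random.default_rng(1)
        n = 8
        state = act.CompetitionState(
            n_units=n, mu=rng.uniform(0, 1, (n, n)) * 0, eta_learn=0.7
        )
        for step in range(30):
            t = _table(rng.uniform(0, 1, n))
            _, state = act.dwalcnn_select(t, state, K=3)
            assert np.all((state.mu >= 0) & (state.mu <= 1))
            assert np.all(np.diag(state.mu) == 0)
            np.testing.assert_allclose(state.mu, state.mu.T)

    def test_asymmetric_mu_rejected(self):
        mu = np.zeros((3, 3))
        mu[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            act.CompetitionState(n_units=3, mu=mu)

    def test_nonzero_diagonal_rejected(self):
        mu = np.eye(3) * 0.2
        with pytest.raises(ValueError, match="diagonal"):
            act.CompetitionState(n_units=3, mu=mu)


class TestCandidates:
    def test_zero_budget_returns_greedy_only(self):
        t = _table([0.8, 0.2, 0.6, 0.4])
        masks = act.generate_candidates(t, K=2, n_candidates=3, time_budget=0.0)
        assert len(masks) == 1
        assert set(masks[0].active) == {0, 2}

    def test_modular_best_candidate_is_top_k(self):
        t = _table([0.9, 0.1, 0.7, 0.3, 0.5])
        masks = act.generate_candidates(t, K=2, n_candidates=3, time_budget=0.05,
                                        seed=0)
        assert set(masks[0].active) == {0, 2}  # MCTS cannot beat modular top-K

    def test_all_masks_respect_budget(self):
        rng = np.random.default_rng(2)
        t = _table(rng.uniform(0, 1, 10))
        masks = act.generate_candidates(t, K=4, n_candidates=5, time_budget=0.05,
                                        seed=1)
        for m in masks:
            assert 1 <= m.a.sum() <= 4


def test_importance_table_from_features():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 3, 600)
    informative = y + 0.2 * rng.normal(size=600)
    noise = rng.normal(size=(600, 3))
    F = np.column_stack([informative, noise])
    table = act.build_importance_table(F, y)
    assert table.n_units == 4
    assert np.argmax(table.mi) == 0
    assert np.all(table.mi >= 0)
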