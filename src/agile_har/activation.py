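"""Dynamic sparse subnetwork activation over the CNN backbone.

Which filters of the backbone's final block fire for a given input is decided
per window under a hard budget of K active units.  Unit utility is the mutual
information between the unit's pooled activation and the class label,
estimated with a Gaussian KDE (Silverman bandwidth); marginal utilities carry
an mRMR-style redundancy penalty standing in for conditional MI under the
local-conditional-independence assumption.  Three selection strategies share
the budget contract 1 <= sum(a) <= K:

* ``greedy``  - hierarchical pruning (top-2K prefilter) + lazy greedy with a
  priority queue, with the classic (1 - 1/e) submodular guarantee;
* ``hgf``     - a heuristic gating function: thresholded scores with
  gradient modulation and an exponentially decaying, budget-aware threshold;
* ``dwalcnn`` - a locally competitive network whose continuous activations
  descend a Hopfield-style Lyapunov energy, with Hebbian-learned
  competition coefficients.

A small Monte-Carlo tree search generates alternative candidate masks when
spare time remains in the frame budget.
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.feature_selection import mutual_info_regression

from .backbone import ConvBackbone, TrainConfig

__all__ = [
    "ActivationUnit",
    "ImportanceTable",
    "ActivationMask",
    "GatingParams",
    "CompetitionState",
    "backbone_train",
    "masked_forward",
    "mi_kde",
    "conditional_gain",
    "lazy_greedy_maximize",
    "greedy_select",
    "hgf_gate",
    "dwalcnn_select",
    "generate_candidates",
    "build_importance_table",
]


@dataclass
class ActivationUnit:
    unit_id: int
    layer: str = "block3"
    granularity: str = "conv_filter"  # conv_filter | fc_row
    param_count: int = 0


@dataclass
class ImportanceTable:
    s: np.ndarray  # per-unit importance score
    mi: np.ndarray  # per-unit label-MI estimate, >= 0
    grad: np.ndarray  # per-unit |dL/ds| proxy

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.mi = np.clip(np.asarray(self.mi, dtype=float), 0.0, None)
        self.grad = np.asarray(self.grad, dtype=float)
        if not (np.all(np.isfinite(self.s)) and np.all(np.isfinite(self.grad))):
            raise ValueError("importance table entries must be finite")

    @property
    def n_units(self) -> int:
        return len(self.s)


@dataclass
class ActivationMask:
    a: np.ndarray  # binary
    K: int
    strategy_tag: str = "greedy"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a).astype(np.int8)
        n_active = int(self.a.sum())
        if not 1 <= n_active <= self.K:
            raise ValueError(
                f"mask must satisfy 1 <= sum(a) <= K, got {n_active} of K={self.K}"
            )

    @property
    def active(self) -> np.ndarray:
        return np.where(self.a == 1)[0]


@dataclass
class GatingParams:
    tau0: float = 1.0
    tau_min: float = 0.05
    beta: float | None = None  # defaults to ln(tau0/tau_min), the decay bound
    gamma: float = 0.1
    T_max: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_min <= self.tau0:
            raise ValueError("need tau0 >= tau_min > 0")
        floor = np.log(self.tau0 / self.tau_min)
        if self.beta is None:
            self.beta = float(floor)
        elif self.beta < floor - 1e-12:
            raise ValueError("beta must satisfy beta >= ln(tau0/tau_min)")


@dataclass
class CompetitionState:
    n_units: int
    mu: np.ndarray = None  # type: ignore[assignment]
    eta_learn: float = 0.1
    lam: float = 0.5
    tau: float = 0.5
    sigmoid_slope: float = 4.0
    h_euler: float = 0.1
    max_iter: int = 200
    tol: float = 1e-4
    neighbors: np.ndarray | None = None  # boolean adjacency; default: all pairs

    def __post_init__(self) -> None:
        if self.mu is None:
            self.mu = np.zeros((self.n_units, self.n_units))
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (self.n_units, self.n_units):
            raise ValueError("mu must be n_units x n_units")
        if not np.allclose(self.mu, self.mu.T):
            raise ValueError("competition coefficients must be symmetric")
        if np.any(np.diag(self.mu) != 0):
            raise ValueError("self-competition (diagonal mu) must be zero")
        if self.neighbors is None:
            self.neighbors = ~np.eye(self.n_units, dtype=bool)


# ---------------------------------------------------------------------------
# backbone wrappers
# ---------------------------------------------------------------------------


def backbone_train(
    train_windows: np.ndarray,
    labels: np.ndarray,
    hyper: TrainConfig | None = None,
    n_classes: int | None = None,
) -> ConvBackbone:
    """Train the 1-D CNN backbone (Adam, lr 0.001, batch 32 by default)."""
    x = np.asarray(train_windows, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    n_classes = n_classes or int(y.max()) + 1
    net = ConvBackbone(
        n_channels=x.shape[1], n_classes=n_classes,
        seed=(hyper.seed if hyper else 0),
    )
    net.fit(x, y, hyper)
    return net


def masked_forward(
    window: np.ndarray, weights: ConvBackbone, mask: ActivationMask
) -> np.ndarray:
    """Forward pass with only the masked final-block filters contributing."""
    x = np.asarray(window, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if mask.a.sum() < 1:
        raise ValueError("all-zero mask violates the safety floor")
    return weights.forward(x, mask=mask.a.astype(np.float32))


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def mi_kde(
    feature_col: np.ndarray,
    labels: np.ndarray,
    bandwidth: float | None = None,
    grid_size: int = 256,
) -> float:
    """KDE estimate of I(f; y) for a scalar feature and discrete labels.

    I = sum_c p(c) * integral p(f|c) log(p(f|c)/p(f)) df, with per-class
    Gaussian KDEs using Silverman's bandwidth h = 1.06 sigma N^(-1/5) unless
    an absolute bandwidth is given, integrated by trapezoid on a shared grid.
    Clipped at zero; a constant feature carries no information.
    """
    f = np.asarray(feature_col, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if len(f) < 20:
        raise ValueError("need at least 20 samples")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    sigma = f.std()
    if sigma < 1e-12:
        return 0.0

    def _kde(vals: np.ndarray) -> gaussian_kde:
        if len(vals) < 3:  # tiny class: replicate so the KDE is defined
            vals = np.repeat(vals, 3)
        if vals.std() < 1e-12:
            # degenerate class: a narrow kernel around the point mass
            vals = vals + np.linspace(-1e-6, 1e-6, len(vals)) * max(sigma, 1.0)
        s = vals.std()
        bw = bandwidth / max(s, 1e-12) if bandwidth is not None else "silverman"
        return gaussian_kde(vals, bw_method=bw)

    pad = 0.15 * (f.max() - f.min() + 1e-12) + 3 * (bandwidth or 1.06 * sigma * len(f) ** -0.2)
    grid = np.linspace(f.min() - pad, f.max() + pad, grid_size)

    p_marg = np.zeros(grid_size)
    per_class = []
    priors = counts / counts.sum()
    for cls, prior in zip(classes, priors):
        dens = _kde(f[y == cls])(grid)
        per_class.append(dens)
        p_marg += prior * dens

    mi = 0.0
    eps = 1e-300
    for dens, prior in zip(per_class, priors):
        integrand = dens * (np.log(dens + eps) - np.log(p_marg + eps))
        mi += prior * np.trapezoid(integrand, grid)
    return float(max(mi, 0.0))


def _feature_mi(fa: np.ndarray, fb: np.ndarray, seed: int = 0) -> float:
    """Continuous-continuous MI (Kraskov kNN estimator) for redundancy terms."""
    return float(
        mutual_info_regression(
            fa.reshape(-1, 1), fb, n_neighbors=3, random_state=seed
        )[0]
    )


def conditional_gain(
    unit_j: int,
    selected_set: list[int] | set[int],
    table: ImportanceTable,
    features: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    rho: float = 1.0,
) -> float:
    """Marginal utility of adding unit j given the selected set.

    Under local conditional independence the conditional MI is approximated
    as I(f_j; y) minus an mRMR-style redundancy penalty
    rho * max_{s in S} I(f_j; f_s), clipped at zero.  With an empty set it
    reduces to the unit's own label MI.
    """
    base = float(table.mi[unit_j])
    if not selected_set:
        return base
    if features is None:
        return max(0.0, base)
    red = max(
        _feature_mi(features[:, unit_j], features[:, s]) for s in selected_set
    )
    return max(0.0, base - rho * red)


# ---------------------------------------------------------------------------
# greedy selection
# ---------------------------------------------------------------------------


def lazy_greedy_maximize(
    gain_fn,
    candidates: np.ndarray,
    K: int,
    time_budget: float | None = None,
) -> list[int]:
    """Lazy greedy maximization of a (sub)modular set function.

    ``gain_fn(j, selected)`` returns the marginal gain of adding j to the
    current selection.  A max-heap of stale upper bounds is re-evaluated only
    when a candidate reaches the top (valid for submodular gains, where
    marginals only shrink).  Ties break by (gain desc, unit id asc) for
    determinism.
    """
    t0 = time.perf_counter()
    selected: list[int] = []
    heap = [(-float(gain_fn(int(j), selected)), int(j), 0) for j in candidates]
    heapq.heapify(heap)
    while heap and len(selected) < K:
        if time_budget is not None and time.perf_counter() - t0 > time_budget:
            break
        neg_gain, j, stamp = heapq.heappop(heap)
        if stamp == len(selected):  # bound is fresh for this selection size
            if -neg_gain <= 0 and selected:
                break  # no remaining positive marginal
            selected.append(j)
        else:
            g = float(gain_fn(j, selected))
            heapq.heappush(heap, (-g, j, len(selected)))
    return selected


def greedy_select(
    table: ImportanceTable,
    K: int,
    features: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    time_budget: float | None = None,
    rho: float = 1.0,
) -> ActivationMask:
    """Hierarchical-pruning greedy selection under budget K.

    Stage 1 keeps the top-2K units by individual label MI; stage 2 runs lazy
    greedy on redundancy-penalized marginal gains; stage 3 attempts
    pair-swap backtracking only while time remains.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = table.n_units
    if K >= n:
        import warnings

        warnings.warn("budget K >= number of units; activating all")
        return ActivationMask(np.ones(n, dtype=np.int8), K=max(K, n), strategy_tag="greedy")
    t0 = time.perf_counter()

    order = np.lexsort((np.arange(n), -table.mi))  # mi desc, id asc
    shortlist = np.sort(order[: 2 * K])

    def gain(j: int, selected: list[int]) -> float:
        return conditional_gain(j, selected, table, features, labels, rho=rho)

    selected = lazy_greedy_maximize(gain, shortlist, K, time_budget)
    if not selected:  # safety floor
        selected = [int(order[0])]

    # stage 3: bounded pair-swap backtracking if budget allows
    if time_budget is not None and time.perf_counter() - t0 < 0.5 * time_budget:
        pool = [int(j) for j in shortlist if j not in selected]
        improved = True
        while improved and time.perf_counter() - t0 < 0.9 * time_budget:
            improved = False
            current = _set_utility(selected, table, features, rho)
            for i, out in enumerate(list(selected)):
                for cand in pool:
                    trial = selected[:i] + selected[i + 1 :] + [cand]
                    if _set_utility(trial, table, features, rho) > current + 1e-12:
                        pool[pool.index(cand)] = out
                        selected = trial
                        improved = True
                        break
                if improved:
                    break

    a = np.zeros(n, dtype=np.int8)
    a[selected] = 1
    return ActivationMask(a, K=K, strategy_tag="greedy")


def _set_utility(
    units: list[int],
    table: ImportanceTable,
    features: np.ndarray | None,
    rho: float,
) -> float:
    total, chosen = 0.0, []
    for j in units:
        total += conditional_gain(j, chosen, table, features, None, rho=rho)
        chosen.append(j)
    return total


# ---------------------------------------------------------------------------
# heuristic gating function
# ---------------------------------------------------------------------------


def hgf_gate(
    table: ImportanceTable,
    params: GatingParams,
    T_used: float,
    K: int,
) -> ActivationMask:
    """Threshold gate a_j = 1[s_j >= tau(t) - gamma * grad_j] with decaying
    threshold tau(t) = max(tau0 exp(-beta T_used/T_max), tau_min), followed by
    margin-ranked sparsity enforcement down to K and a top-1 safety floor."""
    tau = max(
        params.tau0 * np.exp(-params.beta * np.clip(T_used / params.T_max, 0, 1)),
        params.tau_min,
    )
    lam_j = tau - params.gamma * table.grad  # per-unit effective threshold
    margin = table.s - lam_j
    a = (margin >= 0).astype(np.int8)

    if a.sum() > K:  # deactivate lowest-margin activations first
        active = np.where(a == 1)[0]
        order = active[np.lexsort((active, margin[active]))]  # margin asc, id asc
        a[order[: len(active) - K]] = 0
    if a.sum() == 0:  # safety floor: force the single best-scoring unit
        best = int(np.lexsort((np.arange(table.n_units), -table.s))[0])
        a[best] = 1
    return ActivationMask(a, K=max(K, 1), strategy_tag="hgf")


# ---------------------------------------------------------------------------
# competitive-network selection
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * x))


def lyapunov_energy(a: np.ndarray, s: np.ndarray, state: CompetitionState) -> float:
    """Hopfield energy of the competition dynamics:
    V(a) = -s.a + 1/2 a' mu a + tau sum(a) + sum integral_0^{a_j} sig^-1(lam x) dx.
    Descent of V along da/dt = sigma(s - mu a - tau) - lam a is what makes the
    selection dynamics provably convergent."""
    slope, lam = state.sigmoid_slope, state.lam
    ax = np.clip(lam * a, 1e-12, 1 - 1e-12)
    # integral of (1/slope) log(x/(1-x)) under substitution for sig^-1(lam x)
    integ = (ax * np.log(ax) + (1 - ax) * np.log1p(-ax)) / (slope * lam)
    mu = state.mu * state.neighbors
    return float(-s @ a + 0.5 * a @ mu @ a + state.tau * a.sum() + integ.sum())


def dwalcnn_select(
    table: ImportanceTable,
    state: CompetitionState,
    K: int,
    record_energy: bool = False,
) -> tuple[ActivationMask, CompetitionState] | tuple[ActivationMask, CompetitionState, np.ndarray]:
    """Locally competitive selection: Euler-discretized activation dynamics
    da_j/dt = sigma(s_j - sum_k mu_jk a_k - tau) - lam a_j iterated to a fixed
    point, binary mask = top-K of the converged continuous activations, then
    a Hebbian update of the competition coefficients."""
    s = table.s
    n = table.n_units
    if state.n_units != n:
        raise ValueError("competition state size mismatch")
    a = np.full(n, 0.5)
    mu_masked = state.mu * state.neighbors
    energies = []
    for _ in range(state.max_iter):
        drive = s - mu_masked @ a - state.tau
        da = _sigmoid(drive, state.sigmoid_slope) - state.lam * a
        a_new = np.clip(a + state.h_euler * da, 0.0, 1.0)
        if record_energy:
            energies.append(lyapunov_energy(a_new, s, state))
        if np.max(np.abs(a_new - a)) < state.tol:
            a = a_new
            break
        a = a_new

    order = np.lexsort((np.arange(n), -a))  # a desc, id asc
    mask = np.zeros(n, dtype=np.int8)
    mask[order[:K]] = 1
    if mask.sum() == 0:
        mask[order[0]] = 1

    # Hebbian meta-plasticity on co-activations, restricted to neighborhoods
    outer = np.outer(mask, mask).astype(float)
    mu_new = (1 - state.eta_learn) * state.mu + state.eta_learn * outer
    mu_new = np.clip(mu_new, 0.0, 1.0)
    np.fill_diagonal(mu_new, 0.0)
    mu_new = np.where(state.neighbors, mu_new, state.mu)
    mu_new = (mu_new + mu_new.T) / 2
    np.fill_diagonal(mu_new, 0.0)
    new_state = CompetitionState(
        n_units=n, mu=mu_new, eta_learn=state.eta_learn, lam=state.lam,
        tau=state.tau, sigmoid_slope=state.sigmoid_slope,
        h_euler=state.h_euler, max_iter=state.max_iter, tol=state.tol,
        neighbors=state.neighbors,
    )
    out_mask = ActivationMask(mask, K=K, strategy_tag="dwalcnn")
    if record_energy:
        return out_mask, new_state, np.asarray(energies)
    return out_mask, new_state


# ---------------------------------------------------------------------------
# Monte-Carlo candidate generation
# ---------------------------------------------------------------------------


def generate_candidates(
    table: ImportanceTable,
    K: int,
    n_candidates: int = 3,
    time_budget: float = 0.02,
    features: np.ndarray | None = None,
    utility_fn=None,
    seed: int = 0,
    n_rollouts: int = 200,
) -> list[ActivationMask]:
    """MCTS-lite over unit-inclusion decisions.

    UCB1 guides which unit to fix next; rollouts complete the selection to K
    units at random and are scored by the set utility.  The greedy mask is
    always included as the baseline candidate; with no budget it is the only
    one returned.  All returned masks respect sum(a) <= K.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    greedy = greedy_select(table, K, features=features)
    if time_budget <= 0:
        return [greedy]

    util = utility_fn or (lambda units: _set_utility(list(units), table, features, 1.0))
    rng = np.random.default_rng(seed)
    n = table.n_units
    t0 = time.perf_counter()

    scored: dict[tuple[int, ...], float] = {
        tuple(sorted(greedy.active.tolist())): util(greedy.active.tolist())
    }
    # UCB1 statistics per first-move unit
    counts = np.zeros(n)
    values = np.zeros(n)
    total = 0
    for _ in range(n_rollouts):
        if time.perf_counter() - t0 > time_budget:
            break
        total += 1
        ucb = np.where(
            counts > 0,
            values / np.maximum(counts, 1) + np.sqrt(2 * np.log(total) / np.maximum(counts, 1)),
            np.inf,
        )
        first = int(np.argmax(ucb + 1e-12 * table.s))  # score-informed tie-break
        rest = rng.choice(np.delete(np.arange(n), first), size=min(K - 1, n - 1),
                          replace=False) if K > 1 else np.empty(0, int)
        subset = tuple(sorted([first, *rest.tolist()]))
        r = scored.get(subset)
        if r is None:
            r = util(list(subset))
            scored[subset] = r
        counts[first] += 1
        values[first] += r

    ranked = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))
    masks = []
    greedy_key = tuple(sorted(greedy.active.tolist()))
    for subset, _r in ranked[:n_candidates]:
        a = np.zeros(n, dtype=np.int8)
        a[list(subset)] = 1
        tag = "greedy" if subset == greedy_key else "mcts"
        masks.append(ActivationMask(a, K=K, strategy_tag=tag))
    if greedy_key not in {tuple(sorted(m.active.tolist())) for m in masks}:
        masks[-1] = greedy
    return masks


# ---------------------------------------------------------------------------
# importance table construction
# ---------------------------------------------------------------------------


def build_importance_table(
    features: np.ndarray,
    labels: np.ndarray,
    grads: np.ndarray | None = None,
    score_blend: float = 1.0,
) -> ImportanceTable:
    """Score every unit by label MI of its pooled activation.

    ``features``: (N, n_units) unit activations; ``grads``: optional per-unit
    loss-gradient magnitudes (zero if absent).  The importance score ``s`` is
    the MI scaled into [0, 1] (blended with the gradient magnitude when
    provided)."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    mi = np.array([
        mi_kde(F[:, j], labels) if F[:, j].std() > 1e-12 else 0.0
        for j in range(F.shape[1])
    ])
    g = np.zeros_like(mi) if grads is None else np.abs(np.asarray(grads, float))
    top = mi.max() if mi.max() > 0 else 1.0
    s = score_blend * mi / top + (1 - score_blend) * (g / (g.max() + 1e-12))
    return ImportanceTable(s=s, mi=mi, grad=g)
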