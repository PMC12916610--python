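"""Randomized sketch-and-solve PCA with resource-aware dimension selection.

The feature stage turns a sliding window ``X`` (T samples x n channels) into a
short orthogonal feature vector.  A Gaussian sketch compresses the window, the
spectrum is recovered from an SVD of the sketched matrix, and the number of
retained components d* is chosen by a dual-threshold rule: a hard cumulative
variance floor eta_min plus a soft threshold that relaxes toward eta_min as the
per-frame compute budget is consumed.  An early-stopping test on the eigenvalue
tail keeps the selection scan O(d).

Between full refits the eigenvalue estimates are maintained under single-sample
window shifts with a first-order (rank-one perturbation) update, so per-sample
cost stays O(n*d).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlidingWindow",
    "ProjectionModel",
    "DimensionPolicy",
    "SpectrumState",
    "fast_pca_fit",
    "cumulative_variance",
    "soft_threshold",
    "select_dimension",
    "early_stop_check",
    "update_spectrum",
    "project",
    "save_model",
    "load_model",
]


@dataclass
class SlidingWindow:
    X: np.ndarray  # (T, n)
    label: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 2:
            raise ValueError("window must be a T x n array with T >= 2")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("window contains non-finite values")

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass
class DimensionPolicy:
    """Resource-aware retained-dimension policy.

    ``eta_min`` is the hard cumulative-variance floor (0.9 default; 0.95 in
    variance-retention-guarantee mode), ``delta`` the soft-threshold headroom
    (must satisfy 0 < delta < 1 - eta_min), ``d_max`` the dimension cap and
    ``T_max`` the feature-stage time budget in ms.  ``variant`` switches the
    load-decay law used when the dual-threshold rule is bypassed:
    ``linear_decay`` eta(t) = eta_max - alpha * T_used/T_max, or ``sigmoid``
    eta(t) = eta_min + alpha / (1 + exp(-beta (T_max - T_used))).
    """

    eta_min: float = 0.9
    delta: float = 0.05
    d_max: int = 6
    T_max: float = 5.0
    variant: str = "dual_threshold"  # dual_threshold | linear_decay | sigmoid
    eta_max: float = 0.98
    alpha: float = 0.05
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.eta_min < 1:
            raise ValueError("eta_min must lie in (0, 1)")
        if not 0 < self.delta < 1 - self.eta_min:
            raise ValueError("delta must satisfy 0 < delta < 1 - eta_min")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")


@dataclass
class ProjectionModel:
    P: np.ndarray  # (n, d_star), orthonormal columns
    eigvals: np.ndarray  # nonincreasing spectrum estimates
    d_star: int
    gamma: float  # cumulative variance of the d_star components
    k: int
    p: int
    seed: int
    mean: np.ndarray  # column means used for centering during fit
    V_full: np.ndarray  # (n, len(eigvals)) full basis kept for refits/updates
    quality_flag: bool = False  # set when the cap forced gamma below eta_min

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class SpectrumState:
    """Eigen estimate maintained under rank-one window shifts."""

    mean: np.ndarray
    eigvals: np.ndarray
    V: np.ndarray  # (n, d) eigenvector estimates, held fixed between refits
    T: int  # window length the covariance was estimated from
    n_updates: int = 0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fast_pca_fit(
    X: SlidingWindow | np.ndarray,
    k: int = 9,
    p: int = 5,
    seed: int = 0,
    policy: DimensionPolicy | None = None,
    T_used: float = 0.0,
) -> ProjectionModel:
    """Sketch-and-solve PCA of one window.

    A Gaussian test matrix compresses the centered window into an
    ``l = min(n, k + p)``-dimensional range basis Q; the SVD of ``B = Q^T X``
    recovers right singular vectors and eigenvalue estimates (squared singular
    values over T-1).  When ``l >= n`` the sketch spans the full row space and
    the spectrum is exact.  d* is then chosen by :func:`select_dimension`.
    """
    if not isinstance(X, SlidingWindow):
        X = SlidingWindow(np.asarray(X))
    if policy is None:
        policy = DimensionPolicy()
    if k < 1:
        raise ValueError("sketch dimension k must be >= 1")
    T, n = X.T, X.n
    l = min(n, k + p, T)

    mean = X.X.mean(axis=0)
    Xc = X.X - mean

    rng = np.random.default_rng(seed)
    omega = rng.normal(size=(n, l))
    Y = Xc @ omega  # (T, l)
    Q, _ = np.linalg.qr(Y)
    B = Q.T @ Xc  # (l, n)
    # n <= 9 here, so a one-shot SVD of B replaces iterative bidiagonalization
    _, s, Vt = np.linalg.svd(B, full_matrices=False)
    eigvals = s**2 / (T - 1)
    n_keep = min(n, k)
    # rank deficiency: pad the spectrum with zeros rather than fail
    if len(eigvals) < n_keep:
        pad = n_keep - len(eigvals)
        eigvals = np.concatenate([eigvals, np.zeros(pad)])
        Vt = np.vstack([Vt, np.zeros((pad, n))])
    eigvals = np.clip(eigvals[:n_keep], 0.0, None)
    V = Vt[:n_keep].T  # (n, n_keep)

    d_star, flag = select_dimension(eigvals, policy, T_used, return_flag=True)
    gamma = cumulative_variance(eigvals, d_star)
    return ProjectionModel(
        P=V[:, :d_star],
        eigvals=eigvals,
        d_star=d_star,
        gamma=gamma,
        k=k,
        p=p,
        seed=seed,
        mean=mean,
        V_full=V,
        quality_flag=flag,
    )


# ---------------------------------------------------------------------------
# dimension selection
# ---------------------------------------------------------------------------


def cumulative_variance(eigvals: np.ndarray, j: int) -> float:
    """Fraction of total spectral energy in the top ``j`` components.

    An all-zero spectrum (degenerate constant signal) is defined to have
    cumulative variance 1 for every j.
    """
    lam = np.asarray(eigvals, dtype=float)
    if not 1 <= j <= len(lam):
        raise ValueError("j out of range")
    total = lam.sum()
    if total <= 0:
        return 1.0
    return float(lam[:j].sum() / total)


def soft_threshold(T_used: float, policy: DimensionPolicy) -> float:
    """Load-relaxed variance threshold eta_soft = eta_min + delta*(1 - T_used/T_max)."""
    frac = np.clip(T_used / policy.T_max, 0.0, 1.0)
    return policy.eta_min + policy.delta * (1.0 - frac)


def threshold_variant(T_used: float, policy: DimensionPolicy) -> float:
    """The alternative single-threshold laws (linear decay / sigmoid)."""
    if policy.variant == "linear_decay":
        eta = policy.eta_max - policy.alpha * np.clip(T_used / policy.T_max, 0, 1)
    elif policy.variant == "sigmoid":
        eta = policy.eta_min + policy.alpha / (
            1.0 + np.exp(-policy.beta * (policy.T_max - T_used))
        )
    else:
        raise ValueError(f"no single-threshold law for variant {policy.variant!r}")
    return float(np.clip(eta, policy.eta_min, 1.0 - 1e-12))


def early_stop_check(eigvals: np.ndarray, j: int, eta_min: float) -> bool:
    """Tail-bound early stop: true implies the cumulative variance at j
    already meets ``eta_min`` (the remaining d-j eigenvalues, each at most
    lambda_{j+1} by monotonicity, cannot pull it below the floor)."""
    lam = np.asarray(eigvals, dtype=float)
    d = len(lam)
    if not 1 <= j < d:
        raise ValueError("need 1 <= j < d")
    return bool(lam[j] <= (1.0 - eta_min) * lam.sum() / (d - j))


def _scan(lam: np.ndarray, threshold: float, d_max: int) -> int | None:
    """Single O(d) pass returning the smallest j with Gamma_j >= threshold,
    using the tail-bound early stop; None if no j <= d_max qualifies."""
    d = len(lam)
    total = lam.sum()
    if total <= 0:
        return 1
    running = 0.0
    for j in range(1, min(d, d_max) + 1):
        running += lam[j - 1]
        if running / total >= threshold:
            return j
        # tail-bound termination; sound (it implies Gamma_j >= threshold), so
        # the scan never disagrees with a brute-force full scan
        if j < d and early_stop_check(lam, j, threshold):
            return j
    return None


def select_dimension(
    eigvals: np.ndarray,
    policy: DimensionPolicy,
    T_used: float = 0.0,
    return_flag: bool = False,
) -> int | tuple[int, bool]:
    """Dual-threshold retained dimension: d* = max(d_hard, d_soft), capped.

    d_hard is the smallest j whose cumulative variance reaches ``eta_min``;
    d_soft the smallest reaching the load-dependent soft threshold.  If even
    the cap cannot reach ``eta_min`` the cap is returned with the
    quality-degraded flag set.
    """
    lam = np.asarray(eigvals, dtype=float)
    if np.any(lam < 0) or np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigvals must be nonnegative and nonincreasing")
    if policy.variant in ("linear_decay", "sigmoid"):
        eta = threshold_variant(T_used, policy)
        d = _scan(lam, eta, policy.d_max)
        flag = d is None
        d_star = policy.d_max if d is None else d
        return (d_star, flag) if return_flag else d_star

    eta_soft = soft_threshold(T_used, policy)
    d_hard = _scan(lam, policy.eta_min, policy.d_max)
    d_soft = _scan(lam, eta_soft, policy.d_max)
    flag = d_hard is None
    if d_hard is None:
        d_hard = policy.d_max
    if d_soft is None:
        d_soft = policy.d_max
    d_star = min(max(d_hard, d_soft), policy.d_max)
    return (d_star, flag) if return_flag else d_star


# ---------------------------------------------------------------------------
# streaming spectrum maintenance
# ---------------------------------------------------------------------------


def spectrum_state_from_model(model: ProjectionModel, T: int) -> SpectrumState:
    return SpectrumState(
        mean=model.mean.copy(),
        eigvals=model.eigvals.copy(),
        V=model.V_full.copy(),
        T=T,
    )


def update_spectrum(
    state: SpectrumState, x_new: np.ndarray, x_old: np.ndarray
) -> SpectrumState:
    """First-order eigenvalue update for a one-sample window shift.

    Adding x_new and dropping x_old perturbs the sample covariance by a
    rank-two term; to first order each eigenvalue moves by the quadratic form
    of the perturbation with its (fixed) eigenvector:
    lambda_i += ((v_i^T x~_new)^2 - (v_i^T x~_old)^2) / (T - 1), clipped at 0.
    Eigenvectors are not rotated; a periodic full refit bounds the linearized
    drift (see docs/methods.md).
    """
    x_new = np.asarray(x_new, dtype=float)
    x_old = np.asarray(x_old, dtype=float)
    mean = state.mean + (x_new - x_old) / state.T
    c_new = x_new - mean
    c_old = x_old - mean
    proj_new = state.V.T @ c_new
    proj_old = state.V.T @ c_old
    lam = state.eigvals + (proj_new**2 - proj_old**2) / (state.T - 1)
    lam = np.clip(lam, 0.0, None)
    # preserve nonincreasing order (first-order updates may locally reorder)
    lam = np.sort(lam)[::-1]
    return SpectrumState(
        mean=mean, eigvals=lam, V=state.V, T=state.T, n_updates=state.n_updates + 1
    )


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def project(X: SlidingWindow | np.ndarray, model: ProjectionModel) -> np.ndarray:
    """Window summary feature: mean row of the projected window, length d*."""
    if not isinstance(X, SlidingWindow):
        X = SlidingWindow(np.asarray(X))
    if X.n != model.n:
        raise ValueError(
            f"window has {X.n} channels but model was fitted on {model.n}"
        )
    return X.X.mean(axis=0) @ model.P


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: ProjectionModel, path: str) -> None:
    meta = {"d_star": model.d_star, "gamma": model.gamma, "k": model.k,
            "p": model.p, "seed": model.seed, "quality_flag": model.quality_flag}
    np.savez(path, P=model.P, eigvals=model.eigvals, mean=model.mean,
             V_full=model.V_full, meta=json.dumps(meta))


def load_model(path: str) -> ProjectionModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return ProjectionModel(
            P=data["P"], eigvals=data["eigvals"], mean=data["mean"],
            V_full=data["V_full"], d_star=int(meta["d_star"]),
            gamma=float(meta["gamma"]), k=int(meta["k"]), p=int(meta["p"]),
            seed=int(meta["seed"]), quality_flag=bool(meta["quality_flag"]),
        )
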