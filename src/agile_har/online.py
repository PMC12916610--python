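"""Detect-then-update online adaptation under concept drift.

A recursive per-dimension CUSUM with EWMA mean/variance baselines watches the
projected feature stream; a Bonferroni-corrected adaptive threshold controls
the family-wise false-alarm rate across monitored dimensions.  On alarm, the
classifier head is refreshed by ACGD - plain gradient descent on a
ridge-regularized squared loss whose gradient is sketched through a
Johnson-Lindenstrauss random projection, keeping each update episode within a
millisecond-scale budget.  An SPRT (log-likelihood-ratio) CUSUM variant is
provided for known pre/post-change densities.

The CUSUM recursion accumulates standardized deviations with slack kappa:

    S_t(i) = max(0, S_{t-1}(i) + (f_t(i) - mu0(i)) / sigma0(i) - kappa)

where (mu0, sigma0) are the EWMA estimates frozen at the last reset so the
reference does not chase the shift.  The alarm threshold converts the
per-observation Gaussian quantile q = Phi^-1(1 - alpha_err / 2d) into a CUSUM
decision interval through the likelihood-ratio correspondence h = q^2 / (2
kappa), scaled by the EWMA variance ratio sqrt(V_t / V_inf) for
heteroscedasticity robustness (see docs/methods.md for the calibration).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CusumState",
    "DriftAlarm",
    "AcgdConfig",
    "ewma_update",
    "cusum_step",
    "sprt_step",
    "sketch_gradient",
    "acgd_update",
    "monitor_update_loop",
]

VAR_FLOOR = 1e-8


@dataclass
class CusumState:
    d: int
    alpha_ewma: float = 0.1
    kappa: float = 1.0  # slack; delta_min / 2 with delta_min = 2.0
    alpha_err: float = 0.005  # family-wise false-alarm rate
    warmup: int = 30
    S: np.ndarray = None  # type: ignore[assignment]
    mean: np.ndarray = None  # type: ignore[assignment]
    var: np.ndarray = None  # type: ignore[assignment]
    mu0: np.ndarray = None  # type: ignore[assignment]
    sigma0: np.ndarray = None  # type: ignore[assignment]
    t: int = 0
    h: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.alpha_ewma < 1:
            raise ValueError("alpha_ewma must lie in (0, 1)")
        if self.S is None:
            self.S = np.zeros(self.d)
        if self.mean is None:
            self.mean = np.zeros(self.d)
        if self.var is None:
            self.var = np.ones(self.d)
        if self.h is None:
            self.h = np.full(self.d, np.inf)

    @property
    def quantile(self) -> float:
        """Bonferroni-corrected Gaussian quantile Phi^-1(1 - alpha_err/2d)."""
        return float(stats.norm.ppf(1.0 - self.alpha_err / (2 * self.d)))

    @property
    def armed(self) -> bool:
        return self.t >= self.warmup

    def freeze_baseline(self) -> None:
        """Snapshot the running EWMA estimates as the CUSUM reference."""
        self.mu0 = self.mean.copy()
        self.sigma0 = np.sqrt(np.maximum(self.var, VAR_FLOOR))


@dataclass
class DriftAlarm:
    t: int
    dims: tuple[int, ...]
    S_at_alarm: np.ndarray
    h_at_alarm: np.ndarray
    update_ms: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "t": self.t,
                "dims": list(self.dims),
                "S": np.round(self.S_at_alarm, 6).tolist(),
                "h": np.round(self.h_at_alarm, 6).tolist(),
                "update_ms": self.update_ms,
            }
        )


def ewma_update(state: CusumState, f_t: np.ndarray) -> CusumState:
    """Recursive EWMA mean/variance update (variance floored).

    The variance uses the exact-weighted incremental recursion
    v <- (1-a)(v + a (f - mu_{t-1})^2), the standard form whose fixed point
    is the exponentially weighted sample variance (evaluating the innovation
    against the post-update mean instead would shrink it by (1-a)^2).
    """
    f_t = np.asarray(f_t, dtype=float)
    a = state.alpha_ewma
    innov = f_t - state.mean
    state.mean = state.mean + a * innov
    state.var = (1 - a) * (state.var + a * innov**2)
    state.var = np.maximum(state.var, VAR_FLOOR)
    return state


def cusum_step(state: CusumState, f_t: np.ndarray) -> tuple[CusumState, list[DriftAlarm]]:
    """One monitoring step: EWMA update, CUSUM recursion, adaptive threshold.

    During warm-up the statistic accumulates but never alarms; at the end of
    warm-up the baseline (mu0, sigma0) is frozen.  Alarmed dimensions are
    reset to zero and the baseline is re-frozen from the running estimates.
    """
    f_t = np.asarray(f_t, dtype=float)
    if f_t.shape != (state.d,):
        raise ValueError(f"expected feature vector of length {state.d}")
    state.t += 1
    ewma_update(state, f_t)
    if state.mu0 is None or state.t == state.warmup:
        state.freeze_baseline()
    if not state.armed:
        return state, []

    z = (f_t - state.mu0) / state.sigma0
    state.S = np.maximum(0.0, state.S + z - state.kappa)

    # adaptive threshold: LLR decision interval q^2/(2 kappa), modulated by
    # the EWMA variance ratio (V_t / V_inf with V = alpha/(2-alpha) sigma^2)
    q = state.quantile
    v_ratio = np.sqrt(
        np.maximum(state.var, VAR_FLOOR) / np.maximum(state.sigma0**2, VAR_FLOOR)
    )
    state.h = q**2 / (2.0 * state.kappa) * v_ratio

    alarms: list[DriftAlarm] = []
    hit = state.S >= state.h
    if np.any(hit):
        dims = tuple(int(i) for i in np.where(hit)[0])
        alarms.append(
            DriftAlarm(
                t=state.t, dims=dims,
                S_at_alarm=state.S.copy(), h_at_alarm=state.h.copy(),
            )
        )
        state.S[hit] = 0.0
        state.freeze_baseline()
    return state, alarms


def sprt_step(
    S: float,
    y_t: float,
    p0,
    p1,
    h: float,
    clip_nats: float = 50.0,
) -> tuple[float, bool]:
    """Log-likelihood-ratio CUSUM step (SPRT variant).

    ``p0``/``p1`` are callables returning densities under the null and drift
    hypotheses.  Zero densities clip the log ratio at +-clip_nats.
    """
    d0, d1 = float(p0(y_t)), float(p1(y_t))
    if d0 <= 0 or d1 <= 0:
        llr = np.clip(
            (np.log(max(d1, 1e-300)) - np.log(max(d0, 1e-300))),
            -clip_nats,
            clip_nats,
        )
    else:
        llr = np.clip(np.log(d1) - np.log(d0), -clip_nats, clip_nats)
    S_new = max(0.0, S + float(llr))
    return S_new, S_new >= h


# ---------------------------------------------------------------------------
# sketched-gradient updates
# ---------------------------------------------------------------------------


@dataclass
class AcgdConfig:
    r: int | None = None  # projection dim; default ceil(4 ln d) capped at d
    eta_learn: float = 0.001
    max_iter: int = 50
    ridge: float = 1e-3
    seed: int = 0
    update_budget_ms: float = 2.0
    grad_tol: float = 1e-6

    def resolve_r(self, d: int) -> int:
        if self.r is not None:
            if not 1 <= self.r <= d:
                raise ValueError("need 1 <= r <= d")
            return self.r
        return int(min(d, max(2, np.ceil(4.0 * np.log(max(d, 2))))))


def sketch_gradient(G: np.ndarray, P: np.ndarray, r: int) -> np.ndarray:
    """JL-sketched gradient: g~ = (1/r) (G P^T) P, same shape as G.

    ``P`` is an r x d matrix with i.i.d. N(0,1) entries fixed for the update
    episode; E[(1/r) P^T P] = I makes g~ an unbiased compression of G.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    G = np.atleast_2d(np.asarray(G, dtype=float))
    return (G @ P.T) @ P / r


def _ridge_mse_grad(W: np.ndarray, X: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    resid = X @ W - Y
    return 2.0 * (X.T @ resid) / len(X) + 2.0 * ridge * W


def acgd_update(
    W: np.ndarray,
    window_data: np.ndarray,
    labels: np.ndarray,
    cfg: AcgdConfig,
    n_classes: int | None = None,
) -> np.ndarray:
    """Sketched gradient descent on the ridge-regularized squared loss.

    ``W`` maps features to class scores (d x C); the loss is mean squared
    error between ``X W`` and one-hot labels (or raw targets when ``labels``
    is 2-D), plus Tikhonov regularization.  Iterates W <- W - eta * g~ until
    ``max_iter``, gradient norm below tolerance, or the wall-clock budget is
    exhausted.  A zero budget returns W unchanged.
    """
    if cfg.update_budget_ms <= 0:
        return W
    X = np.atleast_2d(np.asarray(window_data, dtype=float))
    if X.size == 0:
        raise ValueError("window_data must be nonempty")
    labels = np.asarray(labels)
    if labels.ndim == 1:
        C = n_classes or int(labels.max()) + 1
        Y = np.zeros((len(labels), C))
        Y[np.arange(len(labels)), labels.astype(int)] = 1.0
    else:
        Y = labels.astype(float)
    W = np.asarray(W, dtype=float).copy()
    d = W.shape[0]
    r = cfg.resolve_r(d)
    rng = np.random.default_rng(cfg.seed)
    P = rng.normal(size=(r, d))  # one-time projection, reused across iterations

    t0 = time.perf_counter()
    for _ in range(cfg.max_iter):
        G = _ridge_mse_grad(W, X, Y, cfg.ridge)
        if np.linalg.norm(G) < cfg.grad_tol:
            break
        g = sketch_gradient(G.T, P, r).T  # sketch along the feature axis
        W -= cfg.eta_learn * g
        if (time.perf_counter() - t0) * 1e3 > cfg.update_budget_ms:
            break
    return W


# ---------------------------------------------------------------------------
# integrated detect-then-update loop
# ---------------------------------------------------------------------------


@dataclass
class MonitorResult:
    model: np.ndarray
    alarms: list[DriftAlarm]
    n_updates: int
    starvations: int


def monitor_update_loop(
    stream_features: np.ndarray,
    labels_delayed: np.ndarray,
    model: np.ndarray,
    cusum_cfg: CusumState | None = None,
    acgd_cfg: AcgdConfig | None = None,
    label_delay: int = 32,
    buffer_len: int = 64,
    n_classes: int | None = None,
) -> MonitorResult:
    """Event-triggered detect-then-update loop over a feature stream.

    Per sample: an O(d) CUSUM step; on alarm, one ACGD episode on the recent
    buffer of (feature, delayed label) pairs, then the statistic is reset
    (which :func:`cusum_step` already performs).  Labels arrive with
    ``label_delay`` samples of lag; an alarm with no labeled data in the
    buffer is logged as starvation and skipped.
    """
    F = np.atleast_2d(np.asarray(stream_features, dtype=float))
    y = np.asarray(labels_delayed)
    n, d = F.shape
    state = cusum_cfg or CusumState(d=d)
    acgd = acgd_cfg or AcgdConfig()
    W = np.asarray(model, dtype=float).copy()

    alarms: list[DriftAlarm] = []
    n_updates = 0
    starvations = 0
    for t in range(n):
        state, new_alarms = cusum_step(state, F[t])
        if not new_alarms:
            continue
        alarm = new_alarms[0]
        avail = t - label_delay + 1  # labels observed so far
        lo = max(0, avail - buffer_len)
        if avail <= lo:
            starvations += 1
            alarms.append(alarm)
            continue
        t0 = time.perf_counter()
        W = acgd_update(W, F[lo:avail], y[lo:avail], acgd, n_classes=n_classes)
        alarm.update_ms = (time.perf_counter() - t0) * 1e3
        n_updates += 1
        alarms.append(alarm)
    return MonitorResult(model=W, alarms=alarms, n_updates=n_updates,
                         starvations=starvations)
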