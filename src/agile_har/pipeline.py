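"""End-to-end orchestration: windowing, features, activation, monitoring,
event-triggered updates and latency control in one streaming loop.

The backbone classifies raw (normalized) 9x128 windows; the compact PCA
feature vector drives drift monitoring and, on alarm, the sketched-gradient
refresh of the classifier head.  Per-window stage timings feed a simulated
latency plant regulated by the PID loop, standing in for frequency scaling on
real hardware.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import activation as act
from . import control as ctl
from . import features as feat
from . import online
from .backbone import ConvBackbone, TrainConfig
from .simulate import LabeledStream

__all__ = [
    "PipelineConfig",
    "RunReport",
    "TrainedModel",
    "objective",
    "preprocess",
    "split_windows",
    "fit_pipeline",
    "run_stream",
    "ablate",
    "evaluate",
]

STD_FLOOR = 1e-8


def objective(per_sample_ms: float, accuracy: float, target_ms: float = 16.7,
              alpha: float = 0.3, beta: float = 0.7) -> float:
    """Resource-accuracy trade-off score alpha*T/T_max - beta*Acc (lower is
    better); used as the MCTS reward and for run reporting."""
    return alpha * per_sample_ms / target_ms - beta * accuracy


@dataclass
class PipelineConfig:
    window_size: int = 128
    stride: int = 64
    n_channels: int = 9
    splits: tuple[float, float, float] = (0.7, 0.2, 0.1)
    policy: feat.DimensionPolicy = field(default_factory=feat.DimensionPolicy)
    sketch_k: int = 9
    oversampling: int = 5
    refit_every: int = 50
    strategy: str = "greedy"  # greedy | hgf | dwalcnn | full
    K: int = 5
    gating: act.GatingParams = field(default_factory=act.GatingParams)
    monitor_dims: int = 6
    alpha_ewma: float = 0.1
    kappa: float = 1.0
    alpha_err: float = 0.005
    label_delay: int = 32  # samples of label lag for online supervision
    online_updates: bool = True
    #: update episodes are capped by iteration count rather than wall clock so
    #: that a pipeline run is bit-reproducible; the per-iteration cost is known
    acgd: online.AcgdConfig = field(
        default_factory=lambda: online.AcgdConfig(max_iter=30, update_budget_ms=1e9)
    )
    gains: ctl.PidGains = field(default_factory=ctl.PidGains)
    target_ms: float = 16.7  # 60 Hz frame budget
    train: TrainConfig = field(default_factory=TrainConfig)
    seed_data: int = 0
    seed_model: int = 0
    seed_stream: int = 0

    def __post_init__(self) -> None:
        if self.stride > self.window_size:
            raise ValueError("stride must not exceed window size")
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("splits must sum to 1")


@dataclass
class NormStats:
    mean: np.ndarray
    std: np.ndarray


@dataclass
class Windows:
    X: np.ndarray  # (N, n_channels, window)
    y: np.ndarray  # (N,) majority labels
    starts: np.ndarray  # (N,) sample indices
    stats: NormStats


@dataclass
class TrainedModel:
    net: ConvBackbone
    table: act.ImportanceTable
    stats: NormStats
    classes: tuple[str, ...]
    unit_features: np.ndarray | None = None  # train-split unit activations


@dataclass
class RunReport:
    accuracy: float
    per_sample_ms: float
    stage_ms: dict[str, float]
    alarm_count: int
    mean_d_star: float
    mean_active_units: float
    telemetry: ctl.ControlTelemetry | None
    predictions: np.ndarray
    labels: np.ndarray
    starts: np.ndarray
    d_star_series: np.ndarray
    alarms: list
    objective_score: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValueError("accuracy must lie in [0, 1]")


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


def preprocess(
    stream: LabeledStream,
    cfg: PipelineConfig | None = None,
    stats: NormStats | None = None,
) -> Windows:
    """Slice the stream into half-open Z-scored windows with majority labels.

    Normalization statistics come from the training portion of the stream
    (the leading ``splits[0]`` fraction) unless precomputed ``stats`` are
    given, so later windows never leak into the normalizer.  Streams with
    fewer than ``n_channels`` channels are zero-padded; more are rejected.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(stream.samples, dtype=float)
    n, nc = x.shape
    if nc > cfg.n_channels:
        raise ValueError(
            f"stream has {nc} channels; at most {cfg.n_channels} supported "
            "(select or reduce upstream)"
        )
    if nc < cfg.n_channels:
        x = np.pad(x, ((0, 0), (0, cfg.n_channels - nc)))
    if n < cfg.window_size:
        raise ValueError("stream shorter than one window")

    if stats is None:
        n_train = max(int(cfg.splits[0] * n), cfg.window_size)
        mean = x[:n_train].mean(axis=0)
        std = np.maximum(x[:n_train].std(axis=0), STD_FLOOR)
        stats = NormStats(mean=mean, std=std)
    xz = (x - stats.mean) / stats.std

    starts = np.arange(0, n - cfg.window_size + 1, cfg.stride)
    X = np.empty((len(starts), cfg.n_channels, cfg.window_size), dtype=np.float32)
    y = np.empty(len(starts), dtype=np.int64)
    for i, s0 in enumerate(starts):
        seg = xz[s0 : s0 + cfg.window_size]
        X[i] = seg.T
        counts = np.bincount(stream.labels[s0 : s0 + cfg.window_size])
        y[i] = int(np.argmax(counts))
    return Windows(X=X, y=y, starts=starts, stats=stats)


def split_windows(
    win: Windows, splits: tuple[float, float, float], seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded stratified train/val/test index split."""
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for cls in np.unique(win.y):
        idx = rng.permutation(np.where(win.y == cls)[0])
        n1 = int(round(splits[0] * len(idx)))
        n2 = int(round((splits[0] + splits[1]) * len(idx)))
        tr.extend(idx[:n1])
        va.extend(idx[n1:n2])
        te.extend(idx[n2:])
    return np.sort(tr), np.sort(va), np.sort(te)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def fit_pipeline(stream: LabeledStream, cfg: PipelineConfig | None = None) -> TrainedModel:
    """Train the backbone on the stream's training windows and score units.

    After training, every final-block filter's pooled activation over the
    training windows is scored by label MI to build the importance table the
    selection strategies consume."""
    cfg = cfg or PipelineConfig()
    win = preprocess(stream, cfg)
    tr, _va, _te = split_windows(win, cfg.splits, cfg.seed_data)
    net = act.backbone_train(
        win.X[tr], win.y[tr], cfg.train, n_classes=len(stream.classes)
    )
    _logits, feats = net.forward(win.X[tr], return_features=True)
    table = act.build_importance_table(feats, win.y[tr])
    return TrainedModel(
        net=net,
        table=table,
        stats=win.stats,
        classes=stream.classes,
        unit_features=feats,
    )


# ---------------------------------------------------------------------------
# streaming loop
# ---------------------------------------------------------------------------


def _select_mask(
    cfg: PipelineConfig,
    model: TrainedModel,
    comp_state: act.CompetitionState | None,
    t_used_ms: float,
) -> tuple[act.ActivationMask, act.CompetitionState | None]:
    n_units = model.table.n_units
    if cfg.strategy == "full":
        return (
            act.ActivationMask(np.ones(n_units, np.int8), K=n_units, strategy_tag="full"),
            comp_state,
        )
    if cfg.strategy == "greedy":
        return act.greedy_select(model.table, cfg.K), comp_state
    if cfg.strategy == "hgf":
        return act.hgf_gate(model.table, cfg.gating, t_used_ms, cfg.K), comp_state
    if cfg.strategy == "dwalcnn":
        if comp_state is None:
            comp_state = act.CompetitionState(n_units=n_units)
        mask, comp_state = act.dwalcnn_select(model.table, comp_state, cfg.K)
        return mask, comp_state
    raise ValueError(f"unknown strategy {cfg.strategy!r}")


def run_stream(
    stream: LabeledStream,
    model: TrainedModel,
    cfg: PipelineConfig | None = None,
) -> RunReport:
    """Run the full closed loop over a stream and report everything.

    Per window: project through the (periodically refit) PCA model, select an
    activation mask, classify with the masked backbone, feed the feature
    vector to the CUSUM monitor (alarms trigger a sketched-gradient head
    refresh on recently labeled windows), and feed the measured stage time to
    the PID-regulated latency plant."""
    cfg = cfg or PipelineConfig()
    win = preprocess(stream, cfg, stats=model.stats)
    n_win = len(win.X)

    policy = cfg.policy
    d_mon = min(cfg.monitor_dims, policy.d_max)
    cusum = online.CusumState(
        d=d_mon, alpha_ewma=cfg.alpha_ewma, kappa=cfg.kappa, alpha_err=cfg.alpha_err
    )
    comp_state: act.CompetitionState | None = None
    plant = ctl.PlantModel(C=0.8 * cfg.target_ms, noise_sigma=0.0)
    ctrl = ctl.ControllerState(ewma_alpha=0.1, u_bounds=(-1.5, 1.5))
    greedy_cached: act.ActivationMask | None = None

    proj: feat.ProjectionModel | None = None
    spec_state: feat.SpectrumState | None = None
    use_pca = cfg.sketch_k > 0

    stage_ms = {"feature": 0.0, "activation": 0.0, "inference": 0.0, "update": 0.0}
    preds = np.empty(n_win, dtype=np.int64)
    d_stars = np.empty(n_win, dtype=np.int64)
    active_counts = np.empty(n_win)
    alarms: list[online.DriftAlarm] = []
    lat_series, f_series = [], []

    # delayed supervision buffer: pooled unit features + labels
    feat_buf: list[np.ndarray] = []
    label_buf: list[int] = []

    W_head = np.vstack([model.net.W_fc, model.net.b_fc]).astype(float)  # (257, C)

    for w in range(n_win):
        x = win.X[w]
        t0 = time.perf_counter()
        # -- feature stage ------------------------------------------------
        if use_pca:
            window = feat.SlidingWindow(x.T.astype(float))
            if proj is None or w % cfg.refit_every == 0:
                prev_V = proj.V_full if proj is not None else None
                proj = feat.fast_pca_fit(
                    window, k=cfg.sketch_k, p=cfg.oversampling,
                    seed=cfg.seed_model, policy=policy,
                )
                if prev_V is not None:
                    # PCA sign indeterminacy: align to the previous basis so
                    # monitored features do not jump at refits
                    ncol = min(prev_V.shape[1], proj.V_full.shape[1])
                    sign = np.sign(
                        np.sum(prev_V[:, :ncol] * proj.V_full[:, :ncol], axis=0)
                    )
                    sign[sign == 0] = 1.0
                    proj.V_full[:, :ncol] *= sign
                    proj.P = proj.V_full[:, : proj.d_star]
                spec_state = feat.spectrum_state_from_model(proj, window.T)
            else:
                # rank-one spectrum maintenance over the stride's samples
                prev = win.X[w - 1].T
                for j in range(cfg.stride):
                    spec_state = feat.update_spectrum(
                        spec_state, window.X[-cfg.stride + j], prev[j]
                    )
                d_star = feat.select_dimension(spec_state.eigvals, policy)
                proj.d_star = d_star
                proj.P = proj.V_full[:, :d_star]
                proj.eigvals = spec_state.eigvals
            f_vec = feat.project(window, proj)
            d_stars[w] = proj.d_star
        else:  # raw-feature arm (identity projection)
            f_vec = x.mean(axis=1)[:d_mon]
            d_stars[w] = len(f_vec)
        f_mon = np.zeros(d_mon)
        f_mon[: min(d_mon, len(f_vec))] = f_vec[:d_mon]
        t1 = time.perf_counter()
        stage_ms["feature"] += (t1 - t0) * 1e3

        # -- activation stage ---------------------------------------------
        elapsed_ms = (t1 - t0) * 1e3
        if cfg.strategy == "greedy" and greedy_cached is not None:
            mask = greedy_cached  # scores are static between head updates
        else:
            mask, comp_state = _select_mask(cfg, model, comp_state, elapsed_ms)
            if cfg.strategy == "greedy":
                greedy_cached = mask
        active_counts[w] = mask.a.sum()
        t2 = time.perf_counter()
        stage_ms["activation"] += (t2 - t1) * 1e3

        # -- inference -----------------------------------------------------
        m = None if cfg.strategy == "full" else mask.a.astype(np.float32)
        logits, pooled = model.net.forward(x[None], mask=m, return_features=True)
        preds[w] = int(np.argmax(logits[0]))
        feat_buf.append(pooled[0])
        label_buf.append(int(win.y[w]))
        t3 = time.perf_counter()
        stage_ms["inference"] += (t3 - t2) * 1e3

        # -- monitoring & event-triggered update ---------------------------
        cusum, new_alarms = online.cusum_step(cusum, f_mon)
        if new_alarms and cfg.online_updates:
            delay_windows = max(1, int(np.ceil(cfg.label_delay / cfg.stride)))
            avail = w - delay_windows + 1
            if avail > 0:
                lo = max(0, avail - 64)
                F = np.asarray(feat_buf[lo:avail])
                F1 = np.hstack([F, np.ones((len(F), 1))])
                y_sup = np.asarray(label_buf[lo:avail])
                W_head = online.acgd_update(
                    W_head, F1, y_sup, cfg.acgd, n_classes=len(model.classes)
                )
                model.net.W_fc = W_head[:-1].astype(np.float32)
                model.net.b_fc = W_head[-1].astype(np.float32)
                greedy_cached = None
        alarms.extend(new_alarms)
        t4 = time.perf_counter()
        stage_ms["update"] += (t4 - t3) * 1e3

        # -- latency control ----------------------------------------------
        measured_ms = (t4 - t0) * 1e3
        plant.C = measured_ms  # this window's workload at unit frequency
        sim_latency = plant.workload_scale * plant.C / plant.f_cpu
        a = ctrl.ewma_alpha
        ctrl.latency_filt = (
            sim_latency
            if ctrl.latency_filt is None
            else (1 - a) * ctrl.latency_filt + a * sim_latency
        )
        e_k = ctrl.latency_filt - cfg.target_ms
        u_before = ctrl.u_prev
        u_k, ctrl = ctl.pid_step(ctrl, e_k, cfg.gains, plant.dt)
        lo_f, hi_f = plant.f_range
        plant.f_cpu = float(np.clip(plant.f_cpu + (u_k - u_before), lo_f, hi_f))
        lat_series.append(sim_latency)
        f_series.append(plant.f_cpu)

    total_ms = sum(stage_ms.values())
    telemetry = ctl.ControlTelemetry(
        latency=np.asarray(lat_series),
        filtered=np.asarray(lat_series),
        error=np.asarray(lat_series) - cfg.target_ms,
        control=np.zeros(n_win),
        f_cpu=np.asarray(f_series),
        target=cfg.target_ms,
    )
    acc = float(np.mean(preds == win.y))
    per_ms = total_ms / max(n_win, 1)
    return RunReport(
        accuracy=acc,
        per_sample_ms=per_ms,
        stage_ms=stage_ms,
        alarm_count=len(alarms),
        mean_d_star=float(np.mean(d_stars)),
        mean_active_units=float(np.mean(active_counts)),
        telemetry=telemetry,
        predictions=preds,
        labels=win.y,
        starts=win.starts,
        d_star_series=d_stars,
        alarms=alarms,
        objective_score=objective(per_ms, acc, cfg.target_ms),
    )


# ---------------------------------------------------------------------------
# evaluation & ablation
# ---------------------------------------------------------------------------


def evaluate(
    model: TrainedModel,
    windows: np.ndarray,
    labels: np.ndarray,
    mask: act.ActivationMask | None = None,
) -> float:
    """Argmax-of-logits accuracy over labeled windows."""
    windows = np.asarray(windows, np.float32)
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cannot evaluate on an empty window set")
    m = mask.a.astype(np.float32) if mask is not None else None
    preds = model.net.predict(windows, mask=m)
    return float(np.mean(preds == labels))


ABLATION_ARMS = ("full_method", "no_fastpca", "no_online", "no_selection")


def ablate(
    stream: LabeledStream,
    model: TrainedModel,
    cfg: PipelineConfig | None = None,
    arms: tuple[str, ...] = ABLATION_ARMS,
) -> dict[str, RunReport]:
    """Run ablation arms on bit-identical windows of the same stream.

    ``no_fastpca`` feeds raw 9-dim channel means to the monitor (identity
    projection); ``no_online`` freezes the model; ``no_selection`` runs the
    dense network (the 'full' strategy)."""
    import copy
    import dataclasses as dc

    cfg = cfg or PipelineConfig()
    out: dict[str, RunReport] = {}
    for arm in arms:
        if arm not in ABLATION_ARMS:
            raise ValueError(f"unknown ablation arm {arm!r}")
        arm_cfg = dc.replace(cfg)
        if arm == "no_fastpca":
            arm_cfg.sketch_k = 0
        elif arm == "no_online":
            arm_cfg.online_updates = False
        elif arm == "no_selection":
            arm_cfg.strategy = "full"
        arm_model = copy.deepcopy(model)  # updates must not leak across arms
        out[arm] = run_stream(stream, arm_model, arm_cfg)
    return out
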