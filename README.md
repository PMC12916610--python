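# agile-har

Closed-loop adaptive edge inference for streaming human-activity recognition
from wearable inertial sensors.

Wearable monitoring of fine motor procedures — the motivating case is the six
phases of a clinical needle insertion (*approaching, aiming, searching,
stabilizing, puncture, tremor*) sensed by a 9-channel IMU at 60 Hz — must run
on devices with millisecond frame budgets while the signal itself slowly
changes: sensors age, operators fatigue, behavior drifts. A model that is
merely small is not enough; it has to notice that the world changed, adapt
cheaply, and keep its own compute inside the deadline. This package implements
that closed loop end to end, and ships a physics-flavored stream simulator so
every stage is testable without any external dataset.

## The loop

For each sliding window **X** ∈ ℝ^{T×n} (T = 128 samples, n = 9 channels,
stride 64):

1. **Feature stage** (`features`). Randomized sketch-and-solve PCA: a Gaussian
   sketch compresses the window, an SVD of the sketched matrix recovers the
   eigenvalue estimates λ₁ ≥ λ₂ ≥ …, and the retained dimension d\* is chosen
   by a dual-threshold rule on the cumulative variance
   Γ_j = Σ_{i≤j} λ_i / Σ_i λ_i: a hard floor η_min and a soft threshold
   η_soft(t) = η_min + δ·(1 − T_used/T_max) that relaxes under compute
   pressure, with an O(d) early-stopping scan. Between refits the spectrum is
   maintained under rank-one window shifts.
2. **Sparse activation** (`activation`, `backbone`). A small 1-D CNN
   (64/128/256 filters, kernel 5, BN+ReLU, global average pool, FC head —
   implemented directly on numpy) classifies the raw window, but only K = 5 of
   its 256 final-block filters are active. Units are scored by the KDE-based
   mutual information Î(f_j; y) between their pooled activation and the label;
   selection is a submodular maximization solved by lazy greedy (with the
   (1 − 1/e) guarantee), a heuristic gating function with a decaying
   threshold, or a locally competitive network whose dynamics descend a
   Hopfield-style Lyapunov energy.
3. **Drift monitoring and update** (`online`). A per-dimension CUSUM with
   EWMA baselines, S_t = max(0, S_{t−1} + (f_t − μ₀)/σ₀ − κ), watches the
   feature stream under a Bonferroni-corrected family-wise false-alarm rate.
   On alarm, the classifier head is refreshed by ACGD: gradient descent on a
   ridge-regularized squared loss whose gradient is compressed through a
   Johnson–Lindenstrauss random projection.
4. **Latency control** (`control`). The measured per-window time drives a
   simulated latency plant (T ≈ C/f_cpu, a normalized stand-in for frequency
   scaling) regulated by an incremental PID
   u_k = u_{k−1} + K_p Δe_k + K_i e_k Δt + K_d Δ²e_k/Δt on an EWMA-filtered
   measurement, with Routh–Hurwitz gain checks and a priority-weighted
   frequency allocator with reserve.

`pipeline.run_stream` wires the stages together; `pipeline.ablate` runs the
matched arms (no PCA / no online updates / dense network) on bit-identical
windows.

## Worked example

```python
import numpy as np
from agile_har import simulate as sim, pipeline as pl
from agile_har.backbone import TrainConfig
from agile_har.simulate import DriftSpec, inject_drift

cfg = pl.PipelineConfig()
cfg.train = TrainConfig(epochs=12, seed=0)

train = sim.generate_stream(sim.SimulatorConfig(duration=6000, seed=11))
model = pl.fit_pipeline(train, cfg)                 # CNN + importance table

live = sim.generate_stream(sim.SimulatorConfig(duration=6400, seed=99))
live = inject_drift(live, DriftSpec(onset=3600, kind="mean_shift", magnitude=2.0))

report = pl.run_stream(live, model, cfg)
post = report.starts >= 3600
print(f"accuracy          {report.accuracy:.3f}")
print(f"post-drift acc    {np.mean(report.predictions[post] == report.labels[post]):.3f}")
print(f"alarms            {report.alarm_count}")
print(f"mean d*           {report.mean_d_star:.2f}")
print(f"mean active units {report.mean_active_units:.1f} / 256")
```

prints

```
accuracy          0.566
post-drift acc    0.333
alarms            3
mean d*           4.15
mean active units 5.0 / 256
```

Read: on a held-out stream carrying a 2σ mean shift at sample 3600, the
greedy K = 5 subnetwork classifies the six phases while the monitor raises 3
alarms (the drift, promptly); each alarm triggers a head refresh on recently
labeled windows. The feature stage keeps ~4 of 9 dimensions on average. The
same run with updates disabled drops to 0.286 post-drift accuracy (and the
dense no-update arm to 0.167; `pipeline.ablate` reports the matched
comparison), so the detect-then-update loop is what preserves usefulness
after the shift. Accuracy of the dense, drift-free
configuration on a fresh stream is ≈ 0.97 (`strategy="full"`).

A CLI mirrors the library:

```bash
agile-har simulate --out stream.npz --seed 17 --duration 6000
agile-har train --stream stream.npz --out model/ --epochs 12
agile-har run-stream --stream stream.npz --model model/ --strategy greedy
agile-har stress-test --seeds 20
```

## Scope

The simulator makes no biomechanical fidelity claims — it reproduces the
*statistical* structure the method assumes (low intrinsic dimension,
harmonic tremor, drift), see `docs/methods.md` for what that does and does
not validate. Real DVFS actuation is replaced by the simulated plant;
loaders for external HAR benchmarks are out of scope.
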