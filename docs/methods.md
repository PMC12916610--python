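# Methods

This note documents the models, numerical choices and open design decisions
behind `agile_har`, in the order data flows through the system. Nothing here
states an empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic IMU stream (`simulate`)

The simulator produces what the rest of the system assumes of real wearable
data, layer by layer:

* **Class base motion.** Each of the six procedure phases is built from three
  latent trajectories (e.g. a sigmoidal translation ramp for *approaching*, a
  decaying oscillation for *stabilizing*) mixed into the 9 channels by a
  fixed 3×9 matrix. Hand motion has few mechanical degrees of freedom, so
  windows have low intrinsic dimension — the property the variance-retention
  claim of the feature stage rests on. The mixing matrix, per-class posture
  offsets and the cross-talk pattern derive from a `geometry_seed` separate
  from the stream seed: sensor geometry is a property of the task, not of a
  recording, and models trained on one stream must transfer to another.
* **Physiological tremor.** A sum of `harmonics` sinusoids at multiples of a
  base frequency drawn uniformly from 8–12 Hz (the physiological range),
  amplitude-modulated at 0.5–1.5 Hz with depth 0.3 to emulate fatigue cycles.
  Tremor couples into channels with triad-specific gains (strong on gyro,
  weak on magnetometer) and a per-class scale (the *tremor* phase trembles
  hardest).
* **Mechanical response.** The tool/tissue interaction at a puncture onset is
  a two-exponential mixture a₁e^{−t/τ₁} + a₂e^{−t/τ₂} with τ₁ = 0.05 s,
  τ₂ = 0.25 s, a₂/a₁ = 0.4 — a fast impact mode plus a slower relaxation.
  The "bimodal exponential" is not given in closed form anywhere we could
  anchor to; this mixture is our interpretation and is exposed in config.
* **Nuisance processes.** Per-channel Gaussian random-walk drift
  (σ = 10⁻³/step), 5% cross-axis mixing, and white noise with σ = 0.1 of the
  (order-1) channel scale. Channel units are dimensionless standardized
  units; the pipeline Z-scores everything anyway.
* **Segments** follow a fixed cyclic class order with lengths uniform in
  2–6 s, which keeps labels balanced. All stochastic draws flow through one
  `numpy` Generator seeded from the config, so (config, seed) is bit-
  reproducible.

Injected drift is expressed in multiples of the pre-onset channel standard
deviation (mean shift, variance scaling, or a linear ramp), matching how the
detector's minimum-detectable-change δ_min is specified.

What the simulator does **not** emulate: true biomechanics, sensor
quantization and dropouts, inter-subject variability beyond parameter
randomization, or label noise. Passing tests therefore demonstrate that the
algorithms behave as designed under the stated statistical structure — not
clinical-grade recognition accuracy.

## Feature stage (`features`)

Sketch-and-solve PCA centers the window, multiplies by a Gaussian test matrix
Ω ∈ ℝ^{n×l}, orthonormalizes Y = X̃Ω, and takes the SVD of B = QᵀX̃; the
right singular vectors give the projection and σ²/(T−1) the eigenvalue
estimates. We use l = min(n, k+p) with oversampling p = 5; at n = 9 the
sketch spans the full row space, so the spectrum is exact to machine
precision (the oracle-equivalence test asserts ≤ 10⁻⁶), and a one-shot SVD of
the 9-column B replaces iterative bidiagonalization — at this width an
iterative solver has nothing to amortize.

Dimension selection takes d\* = max(d_hard, d_soft) capped at d_max = 6,
where d_hard is the smallest j with Γ_j ≥ η_min and d_soft the smallest
reaching the load-relaxed η_soft(t). The scan is a single O(d) pass; a
tail-bound test (λ_{j+1} ≤ (1 − η)Σλ/(d − j) implies Γ_j ≥ η) terminates it
early and provably never changes the answer, which the suite checks against
a brute-force full scan. If even d_max cannot reach η_min, d_max is returned
with a quality-degraded flag rather than an error. Two alternative
single-threshold laws (linear decay, sigmoid) are kept behind
`DimensionPolicy.variant` since both appear in the source material; the
dual-threshold rule is the default because it is the one the selection
algorithm actually executes. Normalization of Γ uses the full estimated
spectrum sum (at n = 9 the estimated and true traces coincide).

Between full refits (every 50 windows in the pipeline) eigenvalues are
maintained under one-sample shifts by the first-order perturbation
λ_i ← λ_i + ((v_iᵀx̃_new)² − (v_iᵀx̃_old)²)/(T−1), clipped at zero and
re-sorted; eigenvectors are held fixed. The linearization accumulates error
when the underlying subspace rotates, which is why refits are periodic and
why the tracking test uses a stationary process (the regime the update
assumes). At refits, new eigenvectors are sign-aligned to the previous basis
so monitored features do not jump.

The window summary feature is the mean of the projected rows, i.e.
mean(X)·P. The reconstruction guarantee the spectrum gives is the classical
one on the centered window, ‖X̃ − X̃PPᵀ‖_F = √(1 − Γ_{d\*})·‖X̃‖_F; no such
bound exists for the mean row (its overlap with the principal subspace is not
constrained by Γ), so the tests assert the Frobenius identity.

## Backbone and sparse activation (`backbone`, `activation`)

The classifier is a three-block 1-D CNN (9→64→128→256 filters, kernel 5,
same padding, BN+ReLU, max-pool 2 after the first two blocks, global average
pool, FC 256→C), trained with Adam (lr 0.001, batch 32). It is implemented
directly on numpy via im2col matmuls with hand-written backprop — at these
shapes dense BLAS is fast enough and the package stays framework-free. BN
statistics freeze at training time; masking zeroes a filter's output *after*
BN+ReLU so running statistics are never corrupted.

**Unit granularity.** A budget of K = 5 over raw parameters cannot coexist
with a CNN of ~10⁵ parameters; the only consistent reading is that selection
operates on structural units — the 256 final-block filters (conv-filter
granularity). K counts active units per selection stage.

**Scoring.** Î(f_j; y) is estimated per unit from the pooled activation with
per-class Gaussian KDEs (Silverman bandwidth 1.06·σ̂·N^{−1/5}), integrating
Σ_c p(c)∫p̂(f|c)log(p̂(f|c)/p̂(f))df by trapezoid on a 256-point grid, clipped
at zero. The estimator is cross-checked against an independent kNN (Kraskov)
estimator in the tests. Conditional gains replace full conditional MI — which
is not estimable in real time — with the mRMR-style surrogate
Î_j − ρ·max_{s∈S}Î(f_j; f_s), ρ = 1, justified by the local
conditional-independence assumption; the feature–feature MI uses the kNN
estimator (a standard step, not the contribution). This surrogate is
monotone in S by construction, which is exactly the diminishing-returns
property the greedy guarantee needs.

**Strategies.** (1) *Greedy*: top-2K prefilter by Î, then lazy greedy with a
priority queue of stale upper bounds (valid under submodularity; verified
identical to naive greedy on 500 instances), then pair-swap backtracking only
while time remains. Ties break by (score desc, unit id asc) everywhere.
(2) *HGF*: a_j = 1[s_j ≥ τ(t) − γ·∂L/∂s_j] with
τ(t) = max(τ₀e^{−βT_used/T_max}, τ_min) and β ≥ ln(τ₀/τ_min) enforced so the
threshold provably reaches its floor by the deadline; over-budget activations
are trimmed in margin order, and an empty gate falls back to the top-scoring
unit (the safety floor). The gradient term ∂L/∂s_j is the absolute loss
gradient w.r.t. the unit's pooled output on the most recent labeled batch.
(3) *DWALCNN*: Euler-discretized competitive dynamics
ȧ_j = σ(s_j − Σ_k μ_jk a_k − τ) − λa_j with logistic slope 4, step h = 0.1,
λ = 0.5, clipped to [0,1], iterated until ‖Δa‖∞ < 10⁻⁴ or 200 steps; binary
mask = top-K of the converged activations; Hebbian update
μ ← (1−η)μ + η·aaᵀ restricted to neighborhoods, clipped, diagonal re-zeroed.
The Lyapunov function we monitor is the standard Hopfield energy
V(a) = −Σs_ja_j + ½Σμ_jk a_j a_k + τΣa_j + Σ∫₀^{a_j}σ⁻¹(λx)dx — the
external-drive term −Σs_ja_j is required for descent (without it V is not
monotone along the dynamics); descent is asserted per step at 10⁻⁹ tolerance
on every tested trajectory. Neighborhoods default to all same-layer units
(the "radius in parameter space" has no defined metric; this is the
conservative choice).

A small MCTS (UCB1 over first-unit choices, random rollouts to K units,
utility as reward) proposes alternative masks when budget remains; the greedy
mask is always among the candidates and is the sole fallback at zero budget.

## Drift detection and online update (`online`)

EWMA baselines use μ̂_t = (1−α)μ̂_{t−1} + αf_t and the exact-weighted variance
recursion v_t = (1−α)(v_{t−1} + α(f_t − μ̂_{t−1})²) with α = 0.1 and a 10⁻⁸
floor. (Evaluating the innovation against the post-update mean instead would
shrink the stationary estimate by (1−α)² ≈ 19%; the exact-weighted form is
the standard estimator.) The CUSUM recursion accumulates deviations
standardized by the baseline (μ₀, σ₀) frozen at the last reset — a reference
that chases the shift cannot detect it — with slack κ = δ_min/2 = 1.

**Threshold calibration.** The per-observation Bonferroni quantile
q = Φ⁻¹(1 − α_err/2d) (3.2905 at α_err = 0.005, d = 5) is a bound on a single
standardized deviation, not on a cumulative statistic; applied directly it
would alarm every ~20 samples on stationary data. We convert it to a CUSUM
decision interval through the likelihood-ratio correspondence: the
standardized CUSUM with slack κ is 1/(2κ) times the log-likelihood ratio for
a shift of 2κ, and Wald's bound sets the false-alarm probability of an LLR
test at threshold q² to e^{−q²}. Hence h_t = q²/(2κ)·√(V_t/V_∞), where
V_t = α/(2−α)·σ̂_t² tracks heteroscedasticity and V_∞ = α/(2−α)·σ₀² is its
stationary value, so the ratio is 1 on stationary data. Empirically this
yields ≲ 1 false alarm per 10⁴ samples across 5 dimensions and detection of a
2σ shift within ~10 samples; the suite asserts both, plus the δ−κ growth rate
of the statistic (measured between steps 3 and 15 after onset, away from the
reflecting barrier at zero, where the max(0,·) bias is negligible).

Alarmed dimensions reset to zero and the baseline re-freezes. The SPRT
variant S_t = max(0, S_{t−1} + log p₁(y_t)/p₀(y_t)) is provided for known
pre/post densities, with log-ratios clipped at ±50 nats.

**ACGD.** On alarm, the FC head (256→C plus bias, ~1.5k parameters) is
refreshed by descent on the ridge-regularized MSE between scores and one-hot
labels over the recent buffer of pooled features with delayed labels
(default lag 32 samples). Only the head adapts: it is the part a ≤ 2 ms
budget can afford, and the squared loss on scores is the loss the update is
defined for. The gradient is compressed as g̃ = (1/r)(GPᵀ)P with a Gaussian
P ∈ ℝ^{r×d}, r = ⌈4 ln d⌉ capped at d, drawn once per episode. E[g̃] = G, and
the r-dimensional compression GPᵀ/√r obeys JL norm concentration; the
reconstruction itself carries an extra √(1+d/r) norm factor, which is why the
step size (η = 0.001 by default) matters more than it would for exact
gradients. In the exact-sketch limit (PᵀP = rI) the iteration is gradient
descent and satisfies the classical per-iteration contraction
1 − μ/(L(1+ε)²) with ε = 0; with a fixed Gaussian P the iteration still
converges (the conditioner PᵀP/r is a.s. positive definite) but its rate is
governed by the conditioner's spectrum — the tests assert the bound in the
exact limit and monotone convergence in the Gaussian case.

## Latency control (`control`)

No hardware constants are published for the plant, so it is normalized:
f_cpu ∈ [0.5, 2.0] around nominal 1.0, one control cycle = one 60 Hz frame,
target latency 1.0, C chosen so that the loop starts exactly at the setpoint
(f₀ = C/target = 0.8), measurement noise σ expressed as a fraction of the
target (0.1 in the stress test). The PID is the incremental law above; since
u_k is the positional frequency command, the plant consumes the increment
u_k − u_{k−1} (feeding u_k itself as an increment would double-integrate and
destabilize the loop). Anti-windup suspends the integral term while the
command sits on an actuation bound; deadband and rate limiting exist as
concepts in the source material but are off by default. The Routh check uses
the first-column conditions for s³ + K_p′s² + (K_i′+A)s + K_d′ with A from
the linearization |dT/df|/target at the equilibrium frequency — a stand-in,
since the constant is never computed in the source.

**Settling under noise.** The EWMA-filtered latency has stationary std
σ√(α/(2−α)) ≈ 2.3% of target, so the literal "re-enters and stays within ±5%
forever" criterion is violated eventually by noise alone in any long run
(a ~2.2σ event per cycle). The 5% criterion is therefore implemented with a
50-cycle persistence window: settling is the first post-step cycle from which
the filtered signal remains in band for the whole window. The window length
was chosen from that noise geometry (≫ the filter time constant of ~10
cycles, ≪ the 900-cycle post-step horizon) before the stress test was run.

The stress test (gains 0.5/0.1/0.05, α = 0.1, σ = 0.1, +50% surge at cycle
100 of 1000, 20 seeds) reports median settling, overshoot and steady-state
deviation; `scripts/acceptance.py` recomputes them.

## Pipeline (`pipeline`)

Windows are Z-scored per channel with statistics from the leading training
fraction of the stream only; channel-deficient streams are zero-padded to 9,
wider ones rejected. The backbone consumes raw normalized 9×128 windows; the
PCA feature vector drives monitoring and the head update (the two texts the
architecture must satisfy route the window to the CNN and the feature vector
to selection/monitoring, and this split satisfies both). The projector
refits every 50 windows with rank-one updates in between. Monitoring runs on
the top-d_max projected coordinates (fixed dimension, zero-padded when
d\* < d_max) so the CUSUM state never changes shape. Reported
`per_sample_ms` is the sum of the stage timers (feature, activation,
inference, update) divided by window count, and the suite asserts the
accounting closes to 1%. Within the pipeline, ACGD episodes are capped by
iteration count rather than wall clock — gating on elapsed time would make
the run report depend on machine load, and bit-reproducibility of a full run
given fixed seeds is itself a contract of the system; the wall-clock budget
remains the default for direct `online.acgd_update` use. Each run also
reports the resource–accuracy objective α·T/T_max − β·Acc (α = 0.3, β = 0.7;
lower is better), which doubles as the reward for MCTS candidate search.

Default problem sizes in the examples and tests — 6000-sample training
streams (~92 windows), 12 training epochs, 20 stress-test seeds — are chosen
so the full suite exercises every stage end to end in a few minutes on one
CPU while leaving every statistical margin comfortably wide; all are plain
config fields.

## Known limitations

* The first-order spectrum update degrades under fast subspace rotation;
  refit cadence is the control knob.
* The KDE MI estimator is univariate; joint effects between units are only
  captured through the pairwise redundancy penalty.
* The per-window masked forward pass is a logical mask, not a sparse kernel:
  it saves none of the dense FLOPs in this implementation (masking is about
  selection semantics, not measured speed).
* The latency plant is a normalized simulation; none of the control numbers
  are wall-clock claims about hardware.
* Online adaptation refreshes only the classifier head; drifts that destroy
  the convolutional features themselves (e.g. channel permutation) are
  detectable but not recoverable by this update.
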