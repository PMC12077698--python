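# Methods

This note documents the models, numerical choices and open design
decisions behind `vmdecg`, and what the synthetic study does and does not
demonstrate.

## Membrane model and signal classes

A single excitable membrane patch follows the classical Hodgkin-Huxley
equations

    Cm dV/dt = I - gNa m^3 h (V - ENa) - gK n^4 (V - EK) - gL (V - EL)
    dx/dt    = alpha_x(V) (1 - x) - beta_x(V) x,   x in {m, h, n}

with the standard squid-axon parameter set (Cm = 1 uF/cm^2, gNa = 120,
gK = 36, gL = 0.3 mS/cm^2, ENa = 50, EK = -77, EL = -54.4 mV).  The rate
functions alpha_m and alpha_n have removable singularities at V = -40 and
V = -55 mV; within 1e-7 mV of the pole the analytic limits (1.0 and
0.1 ms^-1) are substituted.

Three signal classes are produced by modulating the equations with the
exponentially attenuated sinusoid `psi(t) = exp(-4 t) sin(2 pi t)`
(t in seconds):

* **model0** — unmodified equations: periodic stimulation produces a
  regular train of action potentials.
* **model1** — the applied current is multiplied by `psi(t)`.  Because
  `psi` is small except within the first fraction of a second of each
  beat, the effective stimulus is strongly suppressed; the trace stays
  near rest with small deflections.
* **model2** — the whole right-hand side of dh/dt is multiplied by
  `psi(t)`, periodically freezing and even reversing sodium-inactivation
  recovery; spikes still fire but with altered repolarization morphology.

`psi`'s time argument restarts at each stimulus-period onset.  A
once-only decaying modulation would make every beat after the first
identical to model0, so a periodized record would carry almost no class
information; restarting per beat keeps the arrhythmic character
stationary across the record.

### Stimulus

The driving current is a periodic rectangular pulse: amplitude
20 uA/cm^2, duration 1 ms, period 300 ms, pulse onset 5 ms into each
period (all configurable).  For a 1 ms pulse the firing threshold of this
membrane is close to 14 uA/cm^2; 20 uA/cm^2 yields a robust
full-overshoot action potential while remaining in a physiological
range.  The 300 ms period (200 beats/min equivalent at the 0D membrane
level) gives exactly 90 samples per beat at the 300 Hz output rate.

### Integration

Fixed-step RK4 at dt = 0.01 ms, then linear resampling of V(t) to
fs = 300 Hz.  The rectangular stimulus is sampled at each step midpoint
and held constant across the step: stage evaluations then never straddle
a pulse edge, the within-step right-hand side is smooth, and the injected
charge is exact whenever the pulse edges lie on the step grid (true for
the defaults).  Step halving changes a 100 ms trace by ~1e-5 mV RMS on
the integrator grid.  Gating variables are clamped to [0, 1] after each
step; the dynamics keep them strictly inside up to roundoff except for
model2, whose sign-flipping dh/dt can graze the boundary.

## Synthetic dataset

The generator emulates records taken at many "representative points" of a
spatially extended excitable medium using a 0D membrane plus per-record
heterogeneity:

* amplitude scale ~ U(0.8, 1.2), applied to the deflection about the
  resting level (the resting potential itself is not scaled);
* circular phase shift ~ U(0, one beat period);
* additive i.i.d. Gaussian noise, sigma = 5 mV by default (an
  SNR-targeting mode is available); the -65 mV level is the signal
  baseline, not the noise mean.

Defaults: 200 representative points per class, 5 noise replicates each,
records of 512 samples (~1.7 s, ~5.7 beats) at 300 Hz — 3000 records,
1000 per class, split 90/10 stratified by label.  Everything is
reproducible from one seed.

What this generator does **not** emulate: spatial conduction and
wavefront propagation, inter-point waveform correlation, lead-projection
effects, baseline wander, or beat-to-beat variability beyond the phase
shift.  The three classes differ by genuinely distinct nonlinear
dynamics, and at sigma = 5 mV they are highly separable; test accuracies
near 100% on this stand-in therefore demonstrate that the pipeline is
correct and learnable end to end, not that it would reach the same
accuracy on clinically recorded signals.

## Variational mode decomposition

The ADMM scheme operates on the non-negative half-spectrum of the
mirror-extended (2N) signal: Wiener-filter mode update with bandwidth
penalty alpha, power-weighted center-frequency update, optional Lagrange
multiplier step tau, convergence when the summed relative mode change
drops below eps = 1e-7 (multiplier denominators are guarded with 1e-16).
Defaults: tau = 0 (noise-robust; the exact-reconstruction constraint is
relaxed), max_iter = 500 (200 in the pipeline), uniform initialization of
the K center frequencies over (0, 0.5) cycles/sample.  Modes are returned
sorted by ascending center frequency, so "IMF1" is always the
lowest-frequency/trend component.  An all-zero input returns K zero
modes, converged.

## Mode-quality indicators

* **Spectral kurtosis**: Hann-windowed short-time transform (window 32
  samples, 50% hop); per bin, `<|X|^4> / <|X|^2>^2 - 2` with the mean
  over frames.  A stationary Gaussian bin gives 0, a deterministic tone
  -1, impulsive content > 0.  The scalar aggregate is the mean over
  strictly positive sub-Nyquist bins — the DC and Nyquist bins are
  real-valued and carry a +1 bias under Gaussian input, so they are
  excluded (also from the kurtogram map).  Zero-power bins are defined as
  SK = 0.
* **KL divergence**: `sum p (ln p - ln q)` in nats, with q floored at
  1e-12 and 0 ln 0 = 0.  The compared distributions are 64-bin amplitude
  histograms of each mode against the source signal on shared bin edges,
  summed over modes.  Which distributions the divergence should compare
  is genuinely open; this reading is isolated in one helper and easy to
  swap.

## Crayfish optimizer

The constants the original formulation names but does not number are
taken from its reference implementation: C1 = 0.2, sigma = 3, mu = 25,
C3 = 3, C2 = 2 - t/T.  Temperature is drawn per individual per
generation.  The foraging food-size ratio `fitness_i / fitness_food` is
implemented verbatim with |fitness_food| floored at 1e-12.  Positions are
clipped to the bounds after every move; single-objective updates are kept
only when they improve the individual.

The multi-objective variant advances the parent population once per
objective (each guided by that objective's best-so-far "food" position),
pools the resulting k*N candidates — exactly the printed expansion, the
parents are not re-injected — deduplicates identical candidates, applies
fast non-dominated sorting, and truncates by the special crowding
distance: max(decision-space, objective-space crowding) when either
exceeds its front average, else min.  Boundary members get infinite
crowding (the NSGA-II convention); front averages are taken over the
finite entries.  On the Schaffer bi-objective this recovers the analytic
Pareto set with hypervolume within ~0.5% of optimal.

## Tuning (K, alpha)

Bi-objective minimization of (aggregate SK, aggregate KL) over integer
K in [3, 8] and real alpha in [500, 5000]; K is searched continuously and
rounded at evaluation, and (K, alpha) evaluations are cached.  The
default desk-scale budget is population 40 x 60 generations (the full
300 x 1000 is available by configuration).  From the returned front one
point is selected by minimal Euclidean distance to the ideal point after
per-objective min-max normalization — a documented stand-in for a
selection step that is otherwise unspecified.  A fully degenerate space
(both ranges single points) short-circuits to direct evaluation.

## Classifier

Tokens are non-overlapping 16-sample frames with all K mode channels
flattened per token (token count is independent of K); each mode channel
is standardized to zero mean/unit variance over the dataset first, since
the trend mode carries the -65 mV baseline and would otherwise dominate
by two orders of magnitude against the unit-scale positional encodings.
The encoder is the standard stack — learned linear embedding to
d_model = 64, sinusoidal positional encodings, 2 blocks of 4-head
scaled dot-product self-attention and a 128-wide position-wise FFN, each
with residual connection and layer normalization — followed by mean
pooling, a fully connected layer and softmax.  Training is cross-entropy
with momentum SGD (the tuned hyperparameters: batch size, learning rate,
epochs, momentum).  Forward and backward passes are explicit NumPy;
gradients are verified against central finite differences in the tests.
One printed form of the multi-head projection applies the Q-projection to
the weight matrix alone; the standard `Attention(Q Wq, K Wk, V Wv)` is
implemented, reading that form as a typographical slip against its cited
source.

The reduced study budget is 5 epochs at batch 32, learning rate 0.01,
momentum 0.9: on the default dataset the training loss reaches ~1e-3
within 2 epochs, so longer schedules change nothing but runtime.  The
ablation harness and the headline accuracy use 10 seeded repetitions per
arm at this matched budget.

## TPE hyperparameter search

Good/bad trial densities with gamma = 0.25 (|good| = max(1, ceil(gamma
n)), loss ties broken by trial order), 24 candidates per step, 10 uniform
start-up trials.  Continuous dimensions use truncated-Gaussian mixtures
(one component per observation plus a uniform prior component; bandwidth
= width/(n+1), floored at 1% of width), categorical dimensions add-one
smoothing, integer dimensions are treated continuously and rounded, and
the learning rate is searched in log10 space (the Jacobian cancels in the
g/l acquisition ratio).  Failed evaluations record loss = +inf and never
enter the good density.  A Gaussian-process/expected-improvement
surrogate is deliberately not implemented; TPE is the optimizer in use.

## MIT-BIH validation path

Optional and offline: a compact reader for the WFDB header, format-212
and format-16 signal layouts and the MIT annotation format is included
(no external reader dependency), plus a format-16 writer used only to
fabricate synthetic test records.  Beats of classes N, V, A are windowed
256 samples around each annotation from the MLII lead, resampled
360 -> 300 Hz, split 80/20 stratified.  Windows crossing record edges are
skipped and counted.  Real-database segmentation choices (lead fallback,
inter-patient splitting) are not standardized here.

## Known limitations

* The synthetic classes are easier to separate than clinical ECG; see
  the dataset section for what accuracy results do and do not show.  In
  particular, at the default noise level all three ablation arms (raw,
  fixed decomposition, tuned decomposition) saturate near 100% accuracy
  and are statistically indistinguishable (paired t-tests
  non-significant), so the mean ranking among them can flip on a single
  misclassified test record — decomposition cannot demonstrate a benefit
  against an already-perfect raw baseline.
* The decomposition is tuned on one representative normal-class record,
  then applied to all records; per-class or per-record tuning is not
  explored.
* The special-crowding-distance front ordering and the Pareto-point
  selection rule are reasonable readings of underspecified procedures;
  alternatives (e.g. knee-point selection) may pick different (K, alpha).
* The classifier's architecture details (pooling, positional encoding,
  depth) are conventional defaults; the source architecture is not
  specified beyond its block diagram.
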