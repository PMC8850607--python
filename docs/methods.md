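# Methods

This note documents the models, numerical choices, and known limitations of
`perclos-eeg`. Everything quantitative stated here is computed by the test
suite or `scripts/acceptance.py`.

## State-transition process

PERCLOS on the 30-second grid follows

    X_i = ½ (1 + tanh(a X_{i−1} + b + ε_{i−1})),   ε ~ N(0, σ²_ε).

The squash keeps trajectories strictly inside (0, 1) for any finite
parameters. Identification inverts the squash, h_i = atanh(2X_i − 1), and
solves the normal equations of h_i on X_{i−1} in closed form; σ²_ε is the
(ddof = 0) variance of the residuals. Observed PERCLOS can equal exactly 0
or 1 (a full minute with eyes open or closed), where atanh diverges, so
values are clipped into [1e−4, 1 − 1e−4] before the transform. The clip
level is irrelevant for series away from the bounds (tested) and bounds the
transformed values by |h| ≤ atanh(1 − 2e−4) ≈ 4.95.

When several sessions are fitted jointly they are concatenated, but
(X_{i−1}, h_i) pairs spanning a session boundary are excluded: there is no
dynamical link between separate drives.

**Dynamics of the reference parameters.** With a = 3.93, b = −1.79,
σ²_ε = 0.03 the deterministic map is bistable: stable fixed points near
X ≈ 0.036 (alert) and X ≈ 0.985 (extremely drowsy), separated by an
unstable point near 0.42. The noise (σ_ε ≈ 0.17 in the latent variable) is
far too small to cross between basins on realistic horizons, so a
self-simulated trajectory occupies one vigilance regime with a narrow
stationary band (sd ≈ 0.014 in the low basin). Two consequences, both
visible in the tests:

* the regressor variance is small, so the slope estimate from a single
  1080-step trajectory has sd ≈ 0.28; averaging ten independent seeds
  brings the mean within ±0.15 of the generating value;
* on the PERCLOS scale the one-step residual is the latent noise times the
  squash derivative, which *grows* from the saturated tail toward
  mid-range. Residuals on real data behave differently at the extremes
  (real PERCLOS pins at exact 0/1, which this model cannot generate); the
  test asserts the model's own geometry.

## Encoder models and selection

Per feature and session, y_k = α x_k + β + v_k with v ~ N(0, σ²), fitted by
closed-form least squares on the feature's natural scale (no z-scoring).
Diagnostics: R², lag-1 residual autocorrelation. Degenerate inputs follow
fixed conventions: a constant PERCLOS regressor raises a singular-fit
error; a constant feature yields α = 0, p = 1, R² = 0. "Constant" is
judged against a relative threshold (1e−9 of the variable's scale) so that
floating-point rounding on replicated values does not masquerade as
variation.

An optional transform search refits log(y) (only when min y > 0) and
exp(y) (only when max|y| < 80, an overflow guard) and keeps the highest R²,
ties to the identity.

Selection is a two-sided t-test on α with L − 2 degrees of freedom at
p < 0.05, applied per feature with no multiple-testing correction — the
raw threshold is part of the method; with 450 features it admits ~5% false
selections by design, which the cross-session consensus then suppresses
(a noise feature significant in all 15 training sessions has probability
0.05¹⁵). A Benjamini–Hochberg step-up is available (`method="bh"`) but off
by default.

For decoding sessions without labels, per-session fits are pooled per
feature: ᾱ and β̄ are means over training sessions, and the pooled variance
adds the cross-session spread of the fitted lines,

    σ²_pool = mean_d [ σ²_d + E_d((α_d − ᾱ) x + (β_d − β̄))² ],

with the inner expectation under session d's PERCLOS moments. This is the
training-data residual variance of the pooled line; features whose slope
flips sign across drivers get a large pooled variance and are automatically
down-weighted in the likelihood. The alternative `decode_mode="calibrated"`
fits the encoders on a labelled prefix of the test session instead.

## Feature extraction

Nine analysis channels: eight scalp electrodes (Cz, Fz, T7, T8, C3, C4,
PO7, PO8) plus EOG, derived as upper minus lower electrode when not
precomputed. Sub-bands delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30 Hz,
isolated by 4th-order Butterworth filters applied forward–backward (zero
phase). Windows are half-open [t, t + 60 s) advancing by 30 s — the same
grid as PERCLOS, so feature rows pair with PERCLOS values.

The 50-feature catalog per channel: for each sub-band, {absolute power
(mean square), relative power (vs the raw window's variance), variance,
skewness, kurtosis, Hjorth mobility, Hjorth complexity, zero-crossing
rate, line length, peak-to-peak, RMS} (44), plus broadband {total power,
spectral entropy, Hjorth mobility, Hjorth complexity, skewness, kurtosis}
(6). Moments are biased sample moments; flat windows take skewness,
kurtosis and mobility 0 by convention. Hjorth mobility uses the discrete
first difference, so a pure tone at f Hz gives 2 sin(πf/fs) ≈ 2πf/fs
(verified). The catalog is this package's explicit choice; it covers the
families that matter downstream (band powers, band skewness, band Hjorth
mobility) and totals 9 × 50 = 450 columns.

PERCLOS from the eyelid trace: a sample is closed when its aperture is at
or below 20% of the session's open-eye baseline, taken as the 95th
percentile of the trace — trackers report aperture on an arbitrary relative
scale, so an absolute threshold would not transfer across sessions. NaN
gaps up to 0.5 s are linearly interpolated; windows still containing
missing samples are NaN and excluded from fits and metrics pairwise.

## Decoder

The filter discretizes PERCLOS on 201 uniform points in
[1e−4, 1 − 1e−4] (grid size and bounds configurable). The transition
kernel follows by change of variables — Gaussian density of atanh(2x′ − 1)
around a x + b times the Jacobian 2/(1 − (2x′ − 1)²) — row-normalized;
σ²_ε = 0 degenerates to a nearest-grid-point delta. Likelihoods are
products of per-feature Gaussians accumulated in log-space; missing feature
values are skipped, zero-variance entries carry no density, and a
numerically annihilated update falls back to the prediction with a logged
warning. The initial prior is uniform (session vigilance unknown at start).

Intervals are central 95% by default, read from a piecewise-linear CDF
that spreads each grid point's mass uniformly over its cell. This matters:
with 28 informative features at the default noise level the posterior sd
(~0.004) is below the grid spacing (0.005), and raw grid-point quantiles
would collapse the interval to a point; the cell-interpolated construction
keeps coverage honest (mean 95.9% over 50 well-specified sessions). A
highest-density construction is available (`interval="hpd"`).

**Resolution limitation.** The filter-vs-brute-force check (total
variation < 1e−3 per step against a 4001-point filter, compared at the
coincident grid points) is run in a mid-range regime where the posterior
spans many cells, isolating recursion correctness. In the reference-
parameter regime the posterior is only ~3 cells wide and the 201-point
representation deviates from the fine grid by TV ~5e−3 — a resolution
effect, not a recursion error; raise `grid_size` when sharper posteriors
must be represented faithfully.

Evaluation reports RMSE of the posterior mean, the percentage of steps
with the truth inside the 95% interval, and both stratified by the true
value over [0, .25), [.25, .5), [.5, .75), [.75, 1].

## Synthetic data

The feature-level generator emulates the application setting: 18 sessions
(15 train + 3 test, test ids 6/9/15) of 59 windows (30-minute drives),
states from the reference recursion with initial PERCLOS uniform in
[0.05, 0.35] (drives start alert), and 450 features of which 28 are
informative — the four biomarker families over their channels
(alpha-band skewness ×9, delta power ×9, theta power ×7, delta Hjorth
mobility ×3) with per-session slope signs drawn at family-specific
positive-slope probabilities (0.73, 0.66 pushes; 0.488, 0.444 pulls).
Slope magnitude 1.0 and observation noise sd 0.02 give encoder R² ≈ 0.3
against the state process's narrow stationary band — comparable to a good
real EEG feature; uninformative features are pure noise at the same scale.
Every session uses an independent RNG substream; output is bit-identical
under a fixed seed.

The raw-signal generator writes per-channel sums of band-limited noise
whose delta and theta amplitudes scale as (1 + PERCLOS) per 30-s block,
a constant beta component, and an alpha component blending symmetric with
skewed innovations so its skewness falls as PERCLOS rises. The eyelid
trace concentrates each block's closure budget into one episode; block
fractions solve a bounded least-squares system so the overlapping-window
closure fraction reproduces the target exactly whenever it is feasible
(overlapping windows cannot change by more than 0.5 per step for any
physical trace).

What passing tests on these data do *not* show: robustness to real EEG
morphology, artifacts, nonstationarity, inter-driver variability beyond
sign flips, or eyelid traces with realistic blink waveforms — the
generator matches the framework's assumptions by construction, so the
tests validate the machinery, not the physiology.

## Problem sizes and defaults

| Parameter | Default | Meaning |
|---|---|---|
| window / step | 60 s / 30 s | shared sliding-window grid |
| closure threshold | 20% of the 95th-percentile baseline | "at least 80% closed" |
| selection threshold | p < 0.05, two-sided, no correction | slope t-test |
| grid | 201 points on [1e−4, 1−1e−4] | posterior support |
| prior | uniform | initial vigilance unknown |
| interval | central 95%, cell-interpolated | credible interval |
| decode mode | pooled | encoder parameters for unlabelled sessions |
| state parameters | a 3.93, b −1.79, σ²_ε 0.03 | generating truth for simulations |

Simulation sizes used by the checks: ten 1080-step trajectories for
parameter recovery, 100k-step runs for the consistency suite, 50 sessions
for calibration, 18 × 59 steps for the end-to-end pipeline — all chosen as
the natural scale of the study design (540 minutes of driving; 30-minute
sessions).
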