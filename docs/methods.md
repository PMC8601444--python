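# Methods

This note documents the models, estimators and numerical choices behind
`bubbleflow`, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Bolus kinetics

### Model

The first-pass transit of a microbubble bolus through a tissue ROI is
modelled by the gamma-variate

I(t) = A (t − t0)^α exp(−(t − t0)/β) for t > t0, and 0 before arrival,

with A the amplitude (arbitrary intensity units), α > 0 the
dimensionless wash-in shape, β > 0 the wash-out time constant (s), and
t0 ≥ 0 the injection-to-arrival lag (s).  The classic three-parameter
form measures time from injection; the explicit t0 is needed because
arrival in the ROI lags injection by several seconds in vivo and a
reported readout ("time of arrival") depends on it.  Useful closed
forms: the peak is at t0 + αβ with value A(αβ)^α e^−α; the integral
over [t0, ∞) is A β^(α+1) Γ(α+1); the model's half-area time from
arrival is β P⁻¹(α+1, ½), the median of a Gamma(α+1, β) distribution
(P is the regularised lower incomplete gamma function, inverted with
`scipy.special.gammaincinv`; agreement with brute-force cumulative
integral inversion is tested to 10⁻³ β).

### Fitting

Non-linear least squares over (α, β, t0) with the amplitude profiled
out linearly at every step (variable projection): given shape
parameters, the optimal A has the closed form ⟨φ, y⟩/⟨φ, φ⟩ with
φ = (t−t0)^α e^−(t−t0)/β, evaluated in log space and rescaled by its
maximum so large α cannot overflow.  This removes one dimension from
the search and makes the fit exactly scale equivariant together with
the internal peak-normalisation of the intensities (scaling the data by
k scales A alone).

Warm start: arrival is located as the first sustained crossing of 10%
of the floor-to-peak range of a 5-sample moving average (the smoothing
prevents single pre-arrival noise spikes from triggering the crossing;
the range-based threshold keeps the crossing meaningful when the noise
floor is a substantial fraction of peak).  The pre-arrival baseline is
the median of the pre-arrival samples that sit within 5% of the
floor-to-peak range — the restriction prevents a curve that rises
immediately (t0 ≈ 0) from donating rising samples to the baseline.
(α, β) are initialised by ordinary least squares on
ln I = ln A + α ln τ − τ/β over the samples above 10% of peak, and t0
at the last near-zero sample before the crossing.  Optimisation uses
`scipy.optimize.least_squares` (trf, tight tolerances), bounds
α ∈ [0.01, 60], β ∈ [0.01, 10 t_end], t0 ∈ [0, t_peak].  Degenerate
input (all zero, or monotone non-increasing from the first sample)
yields a result object with `converged=False` and a diagnostic message
rather than an exception, so cohort runs never abort on a bad curve.

On noiseless model-generated data the fit recovers all parameters to
machine-level accuracy.  At the study's reference conditions (α=2, β=5,
t0=10 s, 2 Hz × 180 s, Gaussian noise 5% of peak) the median relative
errors are ≈7% (α), ≈3% (β) and ≈25% (A).  The large amplitude error is
a property of the estimation problem, not the optimiser: the Cramér–Rao
bound at these conditions gives sd(ln A) ≈ 35% when t0 is unknown
(≈10% when t0 is known), because A trades off almost freely against
(α, t0) through the τ^α factor.  Amplitude-sensitive conclusions should
be drawn from AUC or peak enhancement, which are well conditioned.

### Fit window

By default all samples are fitted.  The cohort pipeline instead fits
the *first pass* only — the curve is truncated once the smoothed
intensity first falls below 25% of its smoothed peak (configurable).
Rationale: recirculation and bound-agent retention are not part of the
single-bolus model; if left in the window, least squares stretches β to
chase the tail and biases every shape-derived rate.  First-pass
restriction is the standard remedy in gamma-variate bolus analysis.

### Perfusion parameters

From a converged fit and the measured TIC:

* **AUC** — closed form A β^(α+1) Γ(α+1); proportional to relative
  blood volume.
* **wash-in rate** — the analytic maximum of dI/dt on the rising limb,
  attained at τ = β(α − √α) for α > 1.  For α ≤ 1 the model's slope
  diverges at onset, so the rate is reported at τ = αβ/2000 (the
  evaluation grid's first point); such fits indicate a near-discontinuous
  wash-in and the value should be read as a floor.
* **wash-out rate** — |dI/dt| at τ = β(α + √α), clamped to the
  acquisition window; reported as a magnitude.
* **time to peak** — t0 + αβ, from injection.
* **time of arrival** — the fitted curve's crossing of 10% of peak
  (threshold configurable), found by bracketed root finding in
  log-time, which is well behaved for small α.
* **peak enhancement** — the fitted maximum (the raw TIC maximum is
  reported alongside; the fitted value is the primary readout because
  the raw maximum is upward-biased by noise).
* **mean transit time (mTT)** — the *measured curve's* half-area time:
  the time at which the cumulative trapezoidal area reaches half its
  total, referenced to a model-free arrival estimate (interpolated
  10%-of-range crossing), after subtracting the pre-arrival mean (the
  mean, not the median, because a clipped or rectified noise floor is
  one-sided and would otherwise bias the area).  This is a deliberate
  design choice: a single gamma-variate cannot represent the late
  plateau produced by adherent targeted agents, so the half-area time
  of the *fitted* curve is nearly blind to retention — the very effect
  mTT is reported for.  The fitted-model statistic is still available
  as `mtt_model`.

Normalising a TIC by its peak changes A and the two rates by that
scale factor and leaves α, β, t0, mTT, time of arrival and time to
peak unchanged (tested).

Tumour volumes from caliper axes use the ellipsoid formula
V = (π/6)·a·b·c.

## Clutter filtering and ASAP

A frame stack is reshaped to its Casorati matrix (pixels × frames).
Tissue clutter is high-amplitude and temporally slow, so it occupies
the leading singular components; microbubble speckle decorrelates
within a few frames and spreads across the spectrum.  The filter
truncates the leading `low_cutoff` components (default 2) and
optionally trailing components; an energy mode instead removes the
smallest leading set holding ≥95% of the squared singular values.  The
decomposition always belongs to the stack being filtered (the filter is
adaptive per acquisition); `fit` exposes the singular spectrum for
threshold inspection.  Output energy never exceeds input energy, and on
≤5×5×10 stacks the filter matches an independently computed
eigendecomposition of the pixel covariance to 10⁻⁸.

ASAP (acoustic sub-aperture processing) takes two stacks reconstructed
from non-overlapping receive sub-apertures: flow signal is common to
both, electronic noise is independent.  The per-pixel image is the
frame-average of a·conj(b), normalised by the product of per-pixel RMS
amplitudes (default), which bounds the magnitude by 1 and equals 1 for
identical noiseless signals.  Background magnitude then decays as
≈0.89/√N_frames (N=360 frames → ≈0.047), while vessel pixels retain
S/(S+σ²) ≈ 1, which is why ASAP contrast exceeds single-aperture power
Doppler whenever power Doppler's background is noise-limited.  Values
in noise-dominated pixels may be negative or complex and are reported
as-is; clamping is a display concern.

## Synthetic scenes

`generate_ceus_scene` emulates a 2 Hz, 180 s, 64×64 bolus acquisition:

* **clutter** — `clutter_rank` (default 2) outer products of smooth
  complex spatial fields with temporal envelopes 1 + 0.05 sin(2πft)
  (f ∈ [0.03, 0.25] Hz, respiration-scale); exactly low rank by
  construction, total RMS `clutter_amplitude` (default 100, i.e. 40 dB
  above flow).
* **flow** — per-vessel-pixel AR(1) complex speckle (lag-one
  correlation `flow_decorrelation`, default 0.6) scaled by the
  peak-normalised bolus (or retention) envelope times `flow_amplitude`
  (default 1); identical in both apertures.
* **noise** — independent complex Gaussian per aperture,
  `noise_sd` = 0.075 by default, chosen so that single-aperture power
  Doppler is itself respectable (vessel/background > 10 dB after
  filtering) and the ASAP advantage is measured against a competent
  baseline rather than a strawman.

The targeted-agent retention model is a minimal bound pool: a fraction
`bound_fraction` of the peak signal accumulates linearly over the
wash-in (ramp c(τ) = min(1, τ/αβ) in arrival-shifted time) and decays
exponentially with `decay_tau`.  It provably lengthens the half-area
time, monotonically in both parameters.  It is a phenomenological
stand-in — no adhesion kinetics, no ultrasound-pressure dependence, no
late-phase destruction — sufficient to give downstream stages a
retention signal of controllable size.

What the generator does **not** emulate: acoustic propagation,
point-spread functions, attenuation, nonlinear bubble oscillation,
tissue motion beyond the smooth clutter envelopes, or beamforming
(stacks are emitted already beamformed, since sub-aperture splitting of
raw channel data is hardware-specific).  Passing tests therefore
demonstrate the correctness and statistical behaviour of the *analysis
chain* under a controlled model of the signal structure, not robustness
to every artefact of real acquisitions.

## Cohort pipeline

Each synthetic subject receives both agents (its own control).
Injection realism enters as jitter: per-injection lognormal amplitude
factor (CV 0.2 — dose and injection-speed variability, the reason TICs
are conventionally peak-normalised), subject-level lognormal (α, β)
factors (CV 0.1, shared by both arms — vascular physiology, cancelled
by pairing), per-injection (α, β) CV 0.03, and per-injection arrival
jitter (sd 2 s).  The pipeline per subject/arm: generate scene → SVD
filter both apertures → save the normalised ASAP image → ROI TIC as the
aperture-mean power converted to envelope amplitude (square root; B-mode
pixel values are envelope amplitudes) → first-pass gamma-variate fit →
perfusion parameters.  Non-converged fits stay in the table flagged and
are excluded from statistics, never dropped silently.  Reruns with the
same config and seed are byte-identical, including the CSV artifacts
(floats written with `%.17g` and re-read with round-trip parsing).

Statistics: paired t-test per parameter (default), unpaired t-test, or
two-way ANOVA (arm × group) with the arm main effect reported.
Bonferroni correction across the six-parameter family is the default;
zero-variance degenerate cases are defined explicitly (identical arms →
t = 0, p = 1).  Under the null (no retention in either arm) the paired
test on mTT rejects at the nominal 5% rate (400-replicate calibration
in the acceptance suite).  At the reference retention settings
(bound fraction 0.2, decay 60 s) the measured mTT prolongation through
the full pipeline is ≈3 s with paired p ≪ 0.01, while wash-in/wash-out
differences remain within their injection-jitter noise — the wash-out
systematic is real but small, and at n=6 it occasionally crosses an
uncorrected 0.05 threshold, which the Bonferroni-corrected family keeps
in check.

## Morphometry

Micrographs are modelled as bright background plus dark Gaussian rings
(σ = 0.3 µm) at the bubble rim — the brightfield appearance of a
micron-scale gas bubble — with Gaussian sensor noise.  Detection:
background flattening (Gaussian, σ = 50 px) → darkness inversion →
light smoothing → robust threshold (median + 6·1.4826·MAD of the
smoothed darkness; rims occupy a tiny area fraction so the MAD is
noise-driven) → hole filling (rings become disks) → connected
components with a minimum-area gate → solidity check, with
watershed-on-distance-transform splitting of merged rims (residual
failures are kept as single objects and logged).  Each object's centre
is the darkness-weighted centroid; its diameter comes from the minimum
of the angularly averaged radial intensity profile (72 rays, 0.25 px
radial step, bilinear interpolation) with parabolic sub-step
refinement — the profile extremum sits exactly at the rim radius for a
radially symmetric rim, so sizing is subpixel and unbiased (measured
|bias| < 0.01 µm at 0.16 µm/px).  A circular-Hough mode is retained as
an integer-radius cross-check.  Objects outside the configured diameter
band are discarded.

Concentration: mean per-FOV count divided by the optical sampling
volume (FOV area × chamber depth, 1 mm³ = 10⁻³ ml) times the dilution
factor.  The chamber depth is an explicit geometry field (default
0.1 mm, the improved-Neubauer haemocytometer) so the formula stays
auditable; a warning is logged when fewer than 10 FOVs are pooled.

## Numerical and degenerate-input conventions

* All randomness flows through one `numpy.random.Generator` per call,
  seeded from the config; no global RNG state is touched.
* `asap_correlation` defines 0/0 pixels (zero variance in either
  stack) as 0.
* `half_auc_time` rejects curves with non-positive total area.
* Stacks are validated on construction (≥2 frames, finite values,
  positive frame rate); filter cutoffs must total fewer than the frame
  count.
* Scene grids default to 64×64 × 360 frames and cohorts to n=6
  subjects; these sizes keep a full paired cohort (12 scenes, 24 SVDs,
  12 fits) at roughly ten seconds on one core while leaving every
  effect of interest measurable.

## Known limitations

* The gamma-variate is a descriptive bolus model: no arterial-input
  deconvolution, no destruction–replenishment kinetics, and no
  late-phase bound-vs-free discrimination.
* The amplitude A is weakly identified when the arrival lag must be
  estimated (see the Cramér–Rao analysis above).
* ROI masks are 2-D and frame-invariant; there is no motion
  correction.
* The bubble detector assumes dark-rimmed, approximately circular
  objects on a slowly varying background; densely overlapping fields
  beyond the watershed's reach are under-counted and logged.
* The retention model is phenomenological; its parameters are not
  interpretable as molecular binding constants.
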