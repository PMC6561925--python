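# Methods

## Physical model

All quantities derive from two assumptions: **quasi-static conduction**
(capacitive, inductive and propagation effects are negligible at
stimulation frequencies, so fields are instantaneous linear functions of
the injected currents) and **Ohmic linearity** (fields scale exactly with
stimulation intensity).  Under them, every location in the conductor
carries a *phasor* — a complex amplitude A·e^{iφ} representing
A·cos(2πft + φ) — and superposed sources add as phasors (`tacswave.phasor`).

Conventions: cosine reference; phases in degrees wrapped to (−180°, +180°];
positive phase = lead.  A zero-magnitude phasor carries an explicit
`defined=False` flag instead of a sentinel phase, so exact cancellations
cannot silently enter phase regressions.  θ = 0° and θ = 360° are the same
physical condition but are kept as distinct sweep entries, as condition
sweeps conventionally include both endpoints.

### Volume conductor

The forward model (`tacswave.conductor`) is a homogeneous semi-infinite
half-space with point current sources on its boundary:
V = I/(2πσr), with σ = 0.275 S m⁻¹ (gray matter) by default.  This replaces
a finite-element head model deliberately: the package's conclusions rest
only on linearity and quasi-statics, which the analytic kernel preserves
while staying closed-form and fast.  Known limitations: no tissue
inhomogeneity or anisotropy, no skull/scalp shunting, electrodes treated as
point sources (the ~1 cm pad radius is small relative to the source–contact
distances used in the fixtures).  Absolute field magnitudes are therefore
not comparable to realistic head models; magnitude *ratios*, phases and all
wave metrics are.

The stimulation montage has exactly two active electrodes (the first is the
phase reference at 0°, the second carries the condition phase θ) and one
return electrode whose phasor current is computed from current
conservation, −(I₁ + I₂e^{iθ}), never prescribed.  The electrode pad area
defaults to 3.14 cm² (a 1 cm-radius round pad).  Dose metrics follow from
the sinusoidal waveform: RMS current density = (I/√2)/area and charge
density per condition = current density × epoch duration; for 0.1 mA
peak-to-zero, 3.14 cm² and 30 s these evaluate to 0.225 A m⁻² and
6.76 C m⁻² (6.7558 exactly; quoting the rounded density times 30 s gives
6.75).

The along-track field component uses the sign convention E = −∂V/∂s with s
increasing anterior → posterior, so positive E points posterior.  The
`conductor` module provides the *analytic* directional derivative of the
kernel; the measurement pipeline (`fields.compute_efield`) instead applies
the numerical gradient (central differences at interior contacts, one-sided
at the ends) to recorded voltages, because that is the estimator an
experiment can apply.  The two agree to <1% at interior contacts for the
fixture geometries; the one-sided end estimates carry O(h) truncation error
(~10% at 5 mm spacing), so oracle comparisons of pipeline output use the
discrete-gradient transform of the complex voltage phasors — the gradient
is linear, hence commutes with the phasor representation.

## Synthetic recordings

`tacswave.recordings` renders phasor fields into voltage time series that
emulate stereo-EEG depth recordings during a stimulation sweep.  Protocol
defaults are the standard multi-phase protocol: 10 Hz, 0.1 mA peak-to-zero,
25 conditions (0°–360° in 15° steps), 30 s epochs flanked by 5 s linear
ramps, digitized at 5 kHz and analyzed at 1 kHz.  The native-rate choice of
5 kHz is a fixture convention that exercises the decimation path.

The noise model adds three components chosen to be removed or attenuated by
the 5–20 Hz analysis band, making the pipeline's robustness testable:

| component | default | rationale |
|---|---|---|
| white noise SD | 0.02 mV | tens of µV broadband noise typical of clean intracranial recordings against mV-scale stimulation artifacts |
| mains interference | 0.05 mV at 60 Hz | fixed-phase sinusoid per contact |
| baseline drift | 0.1 mV below 0.5 Hz | low-pass-filtered white noise |

What the generator does **not** emulate: physiological signals (neural
entrainment, oscillations), electrode drift, amplifier saturation,
heartbeat/movement artifacts.  Passing tests therefore demonstrate the
correctness of the measurement chain under controlled conditions, not its
robustness to every artifact class of real recordings.

## Preprocessing

The chain is bandpass → downsample → epoch → demean → interpolate →
rescale (`tacswave.preprocess`): a fourth-order zero-phase forward-reverse
Butterworth bandpass at 5–20 Hz, polyphase anti-aliased decimation to
1 kHz, extraction of the 30 s ramp-free steady segment, per-channel
demeaning, neighbor-mean interpolation of flagged bad contacts, and
rescaling to a 1 mA reporting reference (×10 for a 0.1 mA session).  For
sinusoidal artifacts every step is linear, so demean/rescale order is
immaterial; the order is fixed for determinism.  Edge handling uses
reflective padding of 3× the filter's effective impulse length
(≈ 3·fs/f_low samples), which makes short test fixtures behave like the
long experimental epochs.  Runs of adjacent bad contacts are filled
outside-in, each pass using currently valid neighbors; end contacts copy
their single neighbor.  An "outside gray matter" contact is modeled as a
config exclusion, not an anatomical test.

## Spectral estimation

Amplitude and phase at the stimulation frequency are extracted by
single-frequency complex projection over the largest whole number of
stimulation cycles (default mode `"exact"`).  A literal FFT-bin mode is
also provided: zero-pad to 32 768 (2¹⁵) samples and read the bin nearest
10 Hz.  It is not the default because 10 Hz falls between padded-FFT bins
for typical record lengths (30 000 samples at 1 kHz → bin spacing
≈ 0.0305 Hz), and the mismatched bin incurs both an amplitude bias
(~15% low for a 30 s rectangular window) and a Dirichlet-kernel phase drift
(≈ −53° for that record); the projection mode is exact regardless of bin
placement.  Phases are flagged undefined when the amplitude falls below
10⁻⁹ of the track maximum.

Field strength is the RMS per whole stimulation cycle averaged across
cycles (= amplitude/√2 for a pure sinusoid); trailing partial cycles are
dropped.  The per-condition phase difference Δφ subtracts the most
posterior contact's phase from the most anterior, wrapped to (−180°, 180°]
with no cumulative unwrapping; with several tracks the summary reports the
circular mean of per-track values and retains the per-track values.

## Directionality classification

At each time sample the sign pattern of E along a track classifies the
field: all signs equal → unidirectional; anterior-positive /
posterior-negative → inward (converging); the reverse → outward.  Samples
with |E| below 10⁻⁶ of that contact's own maximum are sign-agnostic, and
classification uses the **dominant-pair rule**: the first and last contacts
with a determinate sign decide, which also resolves multiple noise-induced
sign changes.  All-agnostic samples (the field's zero crossing landing
exactly on a sample) are excluded from the denominator and counted.
Fractions are evaluated over whole cycles only.

For two equal-frequency sinusoids with phase offset d the shared-sign
fraction is 1 − d/180 per cycle, the analytic cross-check used in the
tests: a 90° offset gives 50% unidirectional and 25% each inward/outward.
Fixtures that evaluate these fractions sample the cycle at interval
midpoints, t = (k + ½)/fs — the midpoint quadrature never lands a sample
exactly on a carrier zero crossing, so the discrete fractions equal their
continuous-time values at any sampling rate.

## Traveling-wave metrics

* **Dissimilarity index**: per-contact field time-courses are rectified and
  normalized to their own maxima (absolute-value traces; a signed variant
  is available behind a flag for sensitivity analysis), then for every
  unordered contact pair the squared difference is averaged over time; pair
  means are averaged within each track and track means across tracks.  Zero
  exactly when all contacts peak simultaneously — i.e., when all locations
  share one phase modulo 180°.
* **Spatial-variability index**: at each time step the field-magnitude map
  is min–max rescaled across locations; the SD of the rescaled value across
  time is computed per location and the maximum reported.  Degenerate steps
  (all locations equal within 10⁻¹² of the global maximum — in practice the
  carrier's zero crossings, where the map is pure rounding residue) are
  skipped and counted, never imputed.
* **Phase-gradient regression**: φ_E(x) = r·x + b by OLS on phases unwrapped
  along the track with period 180°: each phase is replaced by the
  representative φ + k·180° nearest the previous contact's unwrapped value.
  The 180° period removes the spurious jumps contributed by sign flips of
  the along-track component (the field direction ambiguity) while also
  handling ordinary 360° wraps; it is valid while true adjacent-contact
  phase steps stay below 90°, i.e. gradients up to 18 deg mm⁻¹ at 5 mm
  spacing — far above the observed range.
* **Speed and detection**: c = f/r with f = 360·f_stim/1000 deg ms⁻¹,
  reported unsigned with the propagation direction as sign(r); r = 0 is
  flagged "no propagation" rather than given an infinite speed.  Detection
  uses the inclusive threshold |r| ≥ 1 deg mm⁻¹ (configurable).

On the symmetric fixture the 0° and 180° conditions have exactly real
phasor fields, hence zero dissimilarity, zero variability index and r = 0;
conditions within ±60° of anti-phase stay below the detection threshold.

## Statistics

Condition curves are fit by least squares with the sinusoid's angular
frequency **fixed** to one period per 360° of θ (y = a₀ + a₁cos θ + b₁sin θ),
which the superposition law predicts for squared magnitudes and which makes
the fit linear in its coefficients; a free-frequency fit would add nothing
but nonconvexity.  Adjusted R² uses p = 1 (linear) or p = 2 (sinusoid)
non-intercept regressors.  The three group tests are implemented from their
defining formulas — Kruskal–Wallis H with tie correction (χ² reference),
Brown–Forsythe as one-way ANOVA on |x − group median| (F reference), and
Watson–Williams with the standard 1 + 3/(8κ̂) concentration correction,
κ̂ obtained by the usual three-branch inversion of the von Mises A(κ) — and
cross-checked in the tests against independent routes (scipy's `kruskal`
and `levene(center="median")`, and a from-scratch resultant-length
computation).  Watson–Williams attaches a warning when the weighted mean
resultant length falls below 0.45, where the F approximation degrades.
p-values are asymptotic tail probabilities.  When the pipeline applies
these tests across a sweep, contacts serve as replicates within condition
groups.

## Problem sizes and determinism

Default protocol parameters are the study conditions above.  The test suite
and worked examples run reduced problem sizes chosen as the package's own
fixtures — sweeps of 3–4 conditions, 2–6 s epochs — which exceed the ≥10
stimulation cycles the spectral estimators need while keeping the suite
fast; the phasor oracle makes the comparisons exact at any size.  Every
random component (noise generation, statistical replicates) is driven by an
explicit integer seed through `numpy.random.default_rng`; identical
configurations and seeds produce bit-identical outputs, which the pipeline
tests assert at the level of written CSV bytes.

## Known limitations

* The half-space conductor reproduces directional and phase structure, not
  absolute magnitudes of realistic heads.
* Only the along-track field component is modeled and analyzed;
  medial–lateral components are out of scope.
* The dissimilarity averaging order (pairs within track, then across
  tracks) is one of two defensible conventions; it is fixed and documented
  here.
* Type-I error calibration of the three tests is verified at one
  representative null configuration (5 groups × 20 samples, 500
  replicates), not across the full design space.
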