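# Methods

This note documents the models implemented in `pawcal`, the defaults chosen
where the assay protocol does not pin a value down, and what the synthetic
validation does and does not demonstrate.

## Measurement model and calibration

Aequorin emits one photon per consumed reporter molecule, so a well holds a
finite photon budget `N0` and the instantaneous fractional consumption rate
`k(t)` (s⁻¹) is the Ca²⁺-dependent quantity. The instrument integrates
light over a 500 ms window every 5 s; the terminal discharge (1 M CaCl₂ /
30% ethanol) saturates the reporter so that the recorded counts exhaust the
budget, which makes the remaining budget at sample *i* computable as the
tail sum of counts from *i* to the end of the run.

The empirical calibration curve is

    pCa = slope · (−log₁₀ k) + intercept,  slope = 0.332588, intercept = 5.5593,

the de-facto standard for plant cytosolic aequorin. The constants are
exposed in `CalibrationParams` so a recalibrated curve can be substituted;
`k_floor` (default 10⁻⁶ s⁻¹) replaces zero-count samples so traces stay on
the full grid for integration, and an optional constant background can be
subtracted (default 0 — no background handling is assumed).

**Forward model and the consumption clock.** The simulator computes
`k = inverse_calibrate(Ca)` per sample, draws Poisson counts with mean
`pool · (1 − exp(−k·w))`, and depletes the pool by the exact factor
`exp(−k·w)`, where `w` is the 500 ms integration window. Using the
collection exposure as the consumption clock expresses the pool in
*collectable-count* units: the tail sum of counts then equals the remaining
pool in expectation, total emitted counts telescope exactly to `N0`, and
the tail-sum calibration is the exact inverse of the forward model. The
alternative — depleting over the full 5 s sampling interval while
collecting over 0.5 s — makes the tail sum underestimate the remaining
budget by the duty-cycle factor 10 and biases every calibrated
concentration by a constant factor; with the ratio definition of `k` used
here, the duty cycle must cancel, which the chosen clock guarantees. To
first order the per-sample mean is `k · pool · w`, the familiar
rate-times-budget form. Within-window Ca²⁺ variation is ignored (the window
is short against all kinetic time constants used).

Round-trip accuracy follows counting statistics: a sample with `N` counts
carries a relative rate error of `1/√N`, attenuated by the calibration
slope to `0.3326/√N` in concentration. At the default pool of 10⁷ counts a
resting baseline of 10⁻⁷ M yields ≈230 counts per window, so ~2% RMS; the
5% acceptance bound on samples with ≥50 counts is the same arithmetic at
the low end. Accuracy degrades as the pool depletes (the tail sum becomes
small and noisy), which is why high-Ca²⁺ runs with small pools are flagged
(`pool_exhausted_before_discharge`).

## Synthetic Ca²⁺ kinetics

No public raw data exist for this assay, and the study conditions specify
kinetic *regimes* rather than numeric amplitudes, so the generator uses a
minimal phenomenological form reproducing both regimes:

    Ca(t) = baseline
          + A_t · norm · (e^(−Δt/τ_decay) − e^(−Δt/τ_rise))   (transient)
          + A_s · (1 − e^(−Δt/τ_sus))                          (sustained)

with `norm` scaling the double exponential to unit peak, so `A_t` is the
peak transient amplitude. Defaults: baseline 10⁻⁷ M (typical plant resting
[Ca²⁺]cyt, within the 5×10⁻⁸–10⁻⁷ M range), transient amplitude 4×10⁻⁷ M,
τ_rise 15 s, τ_decay 90 s — a short-exposure response that dissipates well
within 10 min — and a sustained term (default off; τ 300 s) for the
prolonged-exposure regime. Equal rise and decay constants make the
normalized transient degenerate and are rejected rather than special-cased.

Whole experiments map the energy dose E (J/kg) to kinetics through a
saturating law `AUC_true = AUC_max · E/(E + E_half)` applied to the
amplitudes (analytically, so the true AUC is exact in the ledger).
Defaults `AUC_max = 6×10⁻⁴ M·s` above baseline and `E_half = 10⁵ J/kg` are
consistent with effective powers of order 10 W into 20 mL over 3–30 min and
with sustained responses of a few hundred nM integrated over 30 min. Master
seeds spawn per-well seeds via `numpy.random.SeedSequence`, making plate
runs byte-reproducible.

## Signature metrics

- **Baseline:** mean over [injection − 60 s, injection); all pre-stimulus
  samples if fewer than 3 fall in that window.
- **Onset delay:** first sample above baseline + 3·(pre-stimulus SD) with
  2 consecutive samples above threshold — the persistence rule rejects
  single-sample Poisson excursions. Zero pre-stimulus variance (possible
  only for noiseless synthetic input) falls back to a 5% relative
  threshold, flagged. Non-responders return the censored value
  (window length) with a flag so group statistics remain computable;
  censored delays should be treated as lower bounds.
- **Rise slope:** ordinary least squares from the onset sample to the peak
  sample; zero if the peak precedes or coincides with onset. A max-finite-
  difference definition was rejected as noise-sensitive.
- **AUC:** trapezoid on the native 5 s grid over [injection, injection +
  window], *without* baseline subtraction — the integrated quantity is the
  concentration itself, so a flat baseline contributes `baseline · window`.
  Trapezoid error on the 5 s grid is < 0.1% for the kinetics used (it
  scales with h²·f′(0⁺), dominated by the rise time constant).
- **Epochs:** ties at the peak break to the earliest time; two-dose
  protocols end each epoch at the next injection, and the second epoch's
  baseline comes from the 60 s before the *second* injection, so a slow
  return to baseline after dose 1 raises the reference for dose 2 — a
  deliberate, documented consequence of per-epoch baselining.

## Thermal model and fitting

The model is zero-dimensional (a stirred water volume with one lumped loss
term). `solve_temperature` evaluates the closed form with the analytic
`B → 0` limit; `simulate_ode` integrates the conservative form
d(m·cs·T)/dt = Pin − Rcond(T − Tenv) with `scipy.integrate.solve_ivp`
(RK45, rtol 10⁻¹⁰) and supports a linear mass-loss law `m(t) = m0 − ṁt`
for torch runs that eject water; the two agree to better than 10⁻⁶
relative at zero mass loss, which is the oracle check between them.

Fitting is staged to decouple the parameters: the free decay
(T = Tenv + C·e^(−BΔt), nonlinear least squares) identifies B, hence
Rcond = B·m0·cs; the heating phase with B fixed is then *linear* in
(T0, A), solved by least squares, giving Pin = A·m0·cs − Rcond·Tenv. The
ambient temperature is a measured input, not a fitted parameter — with
short series, Tenv and B are poorly separable. A non-positive decay
estimate triggers a lossless linear-heating fallback (Rcond = 0, flagged).
Defaults: cs = 4186 J·kg⁻¹·K⁻¹; water mass 0.02 kg for DBD treatments
(20 mL aliquots) and 0.05 kg for the plasma torch (50 mL). Temperatures
are °C throughout; only differences enter the model.

The dose is `Pin · activation_time / m0` (J/kg). Effective power is
equated with the fitted Pin; evaporative losses during activation are not
separated from the conductive loss term.

## Statistics

Pairwise comparisons use Student's pooled-variance t-test, matching the
assay's reporting convention; no multiplicity correction is applied by
default (`welch=True` and `holm=True` are available). Degenerate pairs with
zero pooled variance return p = 1 (equal means) or p = 0, with a warning.

The compact letter display uses insert-and-absorb: starting from one letter
covering all groups, each significant pair splits every column containing
both members and subset columns are absorbed. The construction guarantees
the defining invariant — two groups share a letter *iff* their test is
non-significant — which the tests verify against a brute-force clique-cover
oracle on the non-significance graph for up to 6 groups.

Dose–response aggregation joins per-well AUCs to per-treatment doses,
reports n, mean and SE sorted by energy, and drops treatments without a
dose record (with a warning).

## Validation scope and problem sizes

The synthetic generator reproduces the *structure* of the assay — Poisson
photon statistics from a finite pool, the duty-cycled sampling protocol,
exponential heating/cooling with Gaussian sensor noise, between-replicate
variation driven purely by counting noise — but not everything real data
contain: no biological replicate-to-replicate kinetic variability, no
baseline drift or temperature-dependent dark counts, no injection
artefacts, no well-to-well expression differences beyond the gain
invariance the calibration removes by construction. Passing tests therefore
demonstrate the correctness of the analysis chain under the stated
measurement model, not robustness to every instrumental pathology.

Problem sizes used in tests and the acceptance script — 400-sample runs,
6 replicates per group, 200 thermal replicates, 2000 null simulations for
type-I calibration, 200 random significance graphs — were chosen so the
Monte-Carlo standard errors sit well inside the property bounds being
checked (e.g. SE ≈ 0.5% for the type-I rate at 2000 simulations against a
±1% band).

## Known limitations

- The calibration constants are the field-standard pair, not a per-batch
  recalibration; traces calibrated with a different curve are comparable
  only after re-running `calibrate_trace` with the matching parameters.
- The consumption-corrected tail-sum denominator is the only depletion
  correction; no additional fraction-consumed correction is applied.
- The thermal model is lumped; strong spatial gradients (torch plume
  contact) violate its assumptions and surface as residual RMS well above
  the sensor noise.
- Onset delay on the 5 s grid is quantised to the sampling interval;
  sub-interval onset estimation is out of scope.
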