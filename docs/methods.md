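# Methods

## From impedance to permittivity

A two-electrode radiofrequency sweep through the chest yields the complex
impedance `Z(f) = R + jX` per frequency bin. Treating the electrode pair as
a parallel-plate capacitor filled with the probed medium, the complex
relative permittivity is `ε* = 1/(jωC0·Z)` with vacuum capacitance
`C0 = ε0·S/d` (electrode surface `S`, separation `d`, which is measured per
participant). In components, with `ε* = ε′ − jε″`:

    ε′ = −X / ((R²+X²)·2πf·C0),   ε″ = R / ((R²+X²)·2πf·C0).

The reactance keeps its measured sign (capacitive loads have X < 0, making
ε′ positive), and the conversion is strictly bin-wise — no resampling — so
the analytic inverse `R = ε″/(ωC0·|ε*|²)`, `X = −ε′/(ωC0·|ε*|²)` round-trips
to machine precision, which the tests exploit. The ionic conductivity is
derived from the loss factor as `σ = ε0·ε″·2πf`; the permittivity modulus is
`|ε*| = √(ε′²+ε″²)`. ε0 is the fixed CODATA constant, not a parameter.

**Assumptions.** The parallel-plate idealization ignores fringing fields,
electrode–skin contact impedance and the anatomical inhomogeneity of the
thoracic path; these are out of scope. What the geometry gets wrong shows
up as a multiplicative error in ε*, which cancels in the log-domain
location parameters the analysis ultimately relies on.

## Dispersion model

In decimal-log coordinates the dielectric constant of biological media
falls in steps across the RF range. Each step is modelled as a logistic
sigmoid in the log of the squared angular velocity:

    lε′(ω) = lε′∞ + Σₙ Δlε′ₙ / (1 + exp((2·lω − lϖτ²ₙ)·αₙ)),  lω = log10(2πf)

with parameters per term: step Δlε′ₙ > 0 (magnitude of the dispersion in
log units), location lϖτ²ₙ (log of the squared relaxation angular
velocity), slope αₙ > 0. The location parameterization is chosen so that
the relaxation frequency is `fₙ = 10^(lϖτ²ₙ/2)/(2π)` — the sigmoid midpoint
sits exactly at `2·lω = lϖτ²ₙ`. The dielectric constants at the two
relaxations follow from the midpoint identity: `ε′β = 10^(lε′∞+Δlε′β/2)`
and `ε′α = 10^(lε′∞+Δlε′β+Δlε′α/2)` (the α midpoint sits on top of the full
β step).

The model is evaluated and fitted on log10 ε′ only. The loss factor is
deliberately not fitted: at the ionic strengths involved, ε″ is dominated
("masked") by the dc conduction term at low frequency, so σ and ε″ at the
relaxation frequencies are instead read off the measured spectrum by
log-log interpolation (exact at grid nodes, refusing extrapolation).

### Fitting

* Objective: Σ(log10 ε′_obs − lε′_model)², bounded trust-region least
  squares (`scipy.optimize.least_squares`, method `trf`), tolerances
  1e-14 on step/function/gradient.
* Bounds: steps in (0, 10], slopes in (0, 20], locations within the
  observed 2·lω range ± 2, plateau within the observed log ε′ range ± 2.
* Initialization: plateau from the top half-decade of log ε′; locations
  from the deepest local minima of the smoothed derivative d(log ε′)/dlω
  (minimum spacing 0.5 lω units); steps from between-transition plateau
  differences; slopes start at 1. If fewer transitions are detectable than
  terms requested, locations fall back to an equally spaced layout with a
  warning.
* Multi-start: 5 restarts by default, jittered from the initial guess with
  sd 0.25 per parameter using the caller's seed; lowest SSE wins. The fit
  never raises on valid input: if no restart converges it returns
  best-effort parameters flagged `converged=False`.
* Degeneracy: fitted locations closer than 0.1 are merged (summed steps,
  step-weighted location) and the result is flagged `covariance_ok=False`,
  preventing spurious α/β assignment from two sigmoids explaining one step.
* Term labelling: after sorting by location, the lowest-location term is α
  and the next is β. The package default is `n_terms=2`; a third term is
  selectable, but because labelling is positional a low-frequency
  electrode-polarization term would capture the α slot, so three-term fits
  are for exploration rather than the standard summary path.

Under clean conditions the fit is exact: on 64 log-spaced bins over 8
decades with well-separated terms (locations ≥ 4.5 apart) all parameters
are recovered to machine precision; with 1% multiplicative measurement
noise the median relaxation-frequency error is ≈ 0.004 decades.

## Synthetic data generator

The generator emulates the study protocol — 49 subjects, four sweeps each
(empty esophagus, water, orange juice, 1% brine) — so the pipeline can be
exercised end to end.

**Cohort.** `fixture_cohort()` is deterministic (no RNG): per-sex
anthropometric values are placed inside the published bin/range structure
(evenly spaced within each bin∩range, decorrelated across parameters by
fixed stride permutations) so that age-bin counts and the flag totals — 6
smokers (2 M/4 W), 7 digestive-issue (3 M/4 W), 6 reflux-history (2 M/4 W)
— are reproduced exactly, with flags co-assigned to the highest-body-fat
records of each sex. One printed inconsistency (a populated women's
visceral-fat bin lying above the printed range maximum) is resolved toward
the range boundary. `generate_cohort()` is the seeded randomized analogue:
truncated-normal anthropometrics within the per-sex ranges, Bernoulli
smoker/digestive flags at the reference prevalences, and a logistic link
P(reflux) = expit(−2.3 + 0.08·(body_fat − 23) + 1.0·smoker) reflecting the
reported fat/smoking–reflux associations.

**Spectra.** Each sweep embeds two ground-truth dispersion terms:
α at lϖτ² = 7.0 (f_α ≈ 500 Hz, step 2.0, slope 1.0) and β at lϖτ² = 13.5
(f_β ≈ 0.9 MHz, step 1.2, slope 1.2), on lε′∞ = 1.3, spanning ε′ from ≈ 20
at 50 MHz to ≈ 3×10⁴ at 10 Hz — plausible magnitudes for tissue-plus-liquid
at these bands. Per-measurement lognormal/normal jitter (locations sd 0.15,
plateau sd 0.05, steps/slopes 5% relative) models biological and placement
variability. Liquid effects: dc conductivity scales 0.05 / 0.10 / 0.35 /
0.45 S/m for empty/water/juice/brine (ordering by ionic strength with juice
and brine deliberately close; the magnitudes are modelling choices, not
measured values) with 10% lognormal spread, plus small α/β step scalings.
Reflux effects: β location shifted by −0.6 lϖτ² units (≈ halving f_β) and β
step × 1.2, applied after the jitter draw so toggling the flag under a
fixed seed shifts β by exactly the configured amount.

The loss factor is built as `ε″ = σ_dc/(2πf·ε0)` plus one narrow loss peak
per relaxation — Gaussian in log-frequency, width 0.2 decades, height half
the term's linear permittivity drop. A classical Debye tail decays only as
f/fₙ below its peak, which would leave a visible residue on the
conduction-dominated limb; the narrow-peak form keeps the low-frequency
loss exactly dc-conduction-shaped (relative deviation < 1e-6 one decade
below f_α), matching the masking structure the analysis assumes while still
placing loss at the relaxations. The permittivity is then inverted to
(R, X) through the subject's electrode geometry (surface 5 cm², separation
0.0013 × height) and multiplicative Gaussian noise (default sd 1%,
independent across bins and between R and X) is applied — the simplest
model of an analyzer's relative accuracy.

**What it does not emulate.** Electrode–skin contact artifacts, anatomical
field geometry, bolus transit dynamics, temperature, a γ dispersion, and
any correlation between anthropometrics and dielectric parameters beyond
the reflux flag. Passing tests therefore demonstrate that the pipeline
recovers what the model family can express under realistic noise — not
that real thoracic spectra obey this model.

## Statistics

One-way ANOVA uses the classical decomposition (F = MS_between/MS_within,
p from the F distribution); it is validated against an independent
implementation and the two-group F = t² identity. Group means are reported
with unprotected Fisher LSD intervals, `t(1−α/2, df_within)·√(MSE/n_g)`,
computed regardless of the omnibus F and without multiplicity correction —
matching the reference procedure — with a Bonferroni option available but
off by default. Liquid-state comparisons are run on log10 of the α-band
conductivity (geometric mean of σ over bins ≤ 1 kHz), log scale because
conductivities are ratio-scaled.

The predictor is OLS with intercept (statsmodels). The response and
features are caller-specified; the documented default — reflux flag on
body fat, visceral fat and smoker — is an assumption, flagged as such in
the output metadata, since the reference analysis names only the tool.

Calibration at the defaults: the liquid-state ANOVA's type-I error under a
null generator (identical liquids, no jitter, noise only) is ≈ 5%; at
study scale (49 × 4) the α-band conductivity ANOVA plus LSD separates all
four liquids in ≥ 95% of seeded studies; a balanced 16-subject design
detects the injected reflux β-shift in the large majority of seeds and not
under a zero shift.

## Problem sizes and determinism

Simulation-based checks use: 1000 random sweeps for round trips, 20
parameter sets for clean recovery, 100 seeds for noisy recovery, 10,000
(tests) / 2,000 (acceptance script) small null studies for type-I
calibration, 500 / 200 studies for separation power, and 9 seeds for the
reflux biomarker — sizes chosen to give stable Monte-Carlo estimates at
the stated tolerances. Every random draw descends from an explicit seed
(`numpy.random.default_rng` / `SeedSequence`); reruns with the same seed
are byte-identical, and pipeline outputs embed the configuration hash and
seed.

## Known limitations

* The α/β labelling is positional; spectra whose lowest dispersion is not
  α (e.g. strong electrode polarization) would be mislabelled in a
  three-term fit.
* Relaxation-point conductivities are interpolated from the measured
  spectrum, not evaluated from the fitted model; with sparse grids the two
  can differ.
* The LSD procedure is intentionally uncorrected for multiplicity.
* The fixture cohort's joint distribution across anthropometrics is
  artificial (only the per-parameter marginals are faithful), so it should
  not be used to study cross-parameter correlations.
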