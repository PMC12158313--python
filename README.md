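# esospec

Analysis pipeline for **esophageal radiofrequency bioimpedance
spectroscopy**: a non-invasive way to detect liquid transit and reflux in
the esophagus by sweeping a small current between two chest electrodes and
reading the dielectric response of the tissue plus whatever liquid is
passing through it.

The package is aimed at researchers working with two-electrode impedance
sweeps (frequency, resistance R, reactance X) who want to go from raw
analyzer output to cohort-level statistics:

1. **Conversion** — each sweep `Z = R + jX` becomes a complex relative
   permittivity via the vacuum capacitance `C0 = ε0·S/d`:

   ```
   ε′(f) = −X / ((R² + X²)·2πf·C0)      dielectric constant
   ε″(f) =  R / ((R² + X²)·2πf·C0)      loss factor
   σ(f)  =  ε0·ε″·2πf                   ionic conductivity (S/m)
   ```

2. **Dispersion decomposition** — the log dielectric constant is fitted
   with a sum of logistic sigmoids in log angular-velocity space,

   ```
   lε′(ω) = lε′∞ + Σₙ Δlε′ₙ / (1 + exp((2·lω − lϖτ²ₙ)·αₙ))
   ```

   one sigmoid per dispersion: α (Hz–kHz, mobile ions) and β (tens of
   kHz–MHz, fixed macromolecular charges). Each term's location parameter
   gives its relaxation frequency `fₙ = 10^(lϖτ²ₙ/2)/(2π)` and the
   dielectric constants at the two relaxations follow from the sigmoid
   midpoints (`ε′β = 10^(lε′∞+Δlε′β/2)`, `ε′α = 10^(lε′∞+Δlε′β+Δlε′α/2)`).

3. **Cohort statistics** — one-way ANOVA with Fisher LSD intervals
   compares relaxation parameters across ingested liquids (empty
   esophagus / water / orange juice / 1% brine) and between reflux
   groups; an OLS multiple-regression predictor links health flags to
   body composition. α-band conductivity separates the liquids; β
   relaxation shifts mark reflux-damaged tissue.

A seeded synthetic-data generator reproduces the structure of the
49-subject study protocol (cohort marginals, four sweeps per subject,
liquid conductivity ordering, reflux β-shifts), so the whole pipeline is
testable without access to raw recordings.

## Worked example

```python
import numpy as np
from esospec import (SensorGeometry, SimulationConfig, simulate_spectrum,
                     fixture_cohort, impedance_to_permittivity,
                     fit_dispersions, relaxation_summary)
from esospec.spectra import MeasurementState
from esospec.synth import DEFAULT_LIQUIDS

cfg = SimulationConfig()                    # 64 log-spaced bins, 10 Hz – 50 MHz
subject = fixture_cohort()[0]
sweep, truth = simulate_spectrum(subject, DEFAULT_LIQUIDS[MeasurementState.WATER],
                                 cfg, seed=7)
geom = SensorGeometry(cfg.electrode_surface, subject.electrode_distance)
perm = impedance_to_permittivity(sweep, geom)
fit = fit_dispersions(perm, n_terms=2, seed=0)
s = relaxation_summary(fit, perm)
print(f"f_alpha = {s.f_alpha:8.1f} Hz   (truth {truth.f_alpha:8.1f})")
print(f"f_beta  = {s.f_beta:8.3g} Hz   (truth {truth.f_beta:8.3g})")
print(f"sigma_alpha = {s.sigma_alpha:.4f} S/m")
```

prints

```
f_alpha =    542.4 Hz   (truth    529.9)
f_beta  = 8.38e+05 Hz   (truth 8.54e+05)
sigma_alpha = 0.1147 S/m
```

i.e. the fit recovers the embedded α relaxation (~530 Hz) and β relaxation
(~0.85 MHz) of this noisy water sweep to about 1–2%, and the conductivity
at the α relaxation reflects the water's dc conductivity scale (0.10 S/m).

The command line exposes the same stages:

```sh
esospec simulate --n-subjects 49 --seed 7 --out-dir study
esospec run --spectra-dir study/spectra --cohort study/cohort.csv --out-dir results
```

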