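# entocalib

Size-based calibration of insect thermal summation constants for forensic
entomology.

## The problem

The minimum postmortem interval (PMI_min) is often bounded by the age of the
oldest immature insect evidence on a body. That age is expressed in
physiological time — accumulated degree-days (ADD) or degree-hours (ADH)
above the species' lower developmental threshold D0 — and the age at adult
emergence is the species' *thermal summation constant* k. But k is a group
average: unusually small or large individuals deviate from it
systematically, because thermal age at emergence correlates with adult body
size (negatively in necrophagous and predatory carrion insects, positively
in parasitoids). Calibrating k against a measured body length previously
required a fitted "k versus size" regression, which exists for almost no
species.

`entocalib` implements a closed-form calibration that needs no such model.
For an individual of length *l* (mm), given the species' published k, its
standard error s_e, the number m of experimental temperatures behind it,
and a literature size range [l_min, l_max]:

    K_c(l) = k ∓ s_e·√(3m) / (l_max − l_min) · (l − (l_max + l_min)/2)

(− for negative, + for positive size correlation). The line passes through
k at the midpoint of the size range and spans s_e·√(3m) across it. It is
the reduced major axis (RMA, model II) regression line implied by three
moment approximations: sd(true k) ≈ s_e·√m/2, sd(l) ≈ √3·(l_max − l_min)/6
and mean(l) ≈ (l_max + l_min)/2, combined with the RMA slope
sign(r)·sd(y)/sd(x).

The package bundles:

* the calibration formula and its moment lemmas (`entocalib.calibration`);
* RMA regression with its product loss (`entocalib.rma`, statsmodels-style
  `RMA(endog, exog).fit()`);
* thermal-time arithmetic — true k of an individual, degree-day
  accumulation over temperature logs, age at collection, a minimal thermal
  summation fitter (`entocalib.thermal`);
* a pre-filled registry of 11 forensically important Central-European
  species with k, s_e, units, size ranges from multiple sources, ecology
  and correlation sign, shipped as an editable CSV (`entocalib.registry`);
* the validation pipeline — half-millimetre length classes, class medians,
  MSE comparison of the RMA / K_c / constant-k models, extreme-size
  subsetting, and one-way ANOVA with Fisher's LSD post hoc under
  Benjamini–Hochberg adjustment (`entocalib.validation`);
* a synthetic-data generator emulating the two beetle rearing datasets the
  calibration was validated on (`entocalib.simulate`).

## Worked example

```python
from entocalib import (age_at_collection, calibrate_k, dd_to_days,
                       get_species, species_formula)

entry = get_species("Necrodes littoralis")
print(species_formula(entry))
kc = calibrate_k(entry.params, entry.selected_range, 21.5,
                 entry.correlation_sign)
print(f"K_c(21.5 mm) = {kc:.2f} ADD  (constant k = {entry.params.k} ADD)")
age = age_at_collection(kc, 120.0)
print(f"age at collection after 120 ADD of rearing: {age:.2f} ADD")
print(f"as days at constant 20 degC (D0 = 8.5): {dd_to_days(age, 20.0, 8.5):.2f} d")
```

prints

```
Kc(l) = 710.82 - 12.05*l [ADD]
K_c(21.5 mm) = 451.82 ADD  (constant k = 469.89 ADD)
age at collection after 120 ADD of rearing: 331.82 ADD
as days at constant 20 degC (D0 = 8.5): 28.85 d
```

A 21.5 mm *N. littoralis* — larger than the population average — is
predicted to emerge about 18 ADD earlier than the species constant k
suggests; subtracting the 120 ADD accrued while rearing the evidence in the
laboratory leaves its physiological age at collection, here ~28.9 days of
equivalent development at a constant 20 °C.

The same is available from the shell:

```sh
entocalib species-formula --species "Necrodes littoralis" --l 21.5
entocalib simulate --species N_littoralis --seed 7 --out records.csv
entocalib validate --records records.csv --species N_littoralis --extremes
```

The `validate` command compares the fitted RMA line, the K_c calibration
and the constant k on class medians; on a synthetic emulation restricted to
unusually small and large beetles it reports MSEs of roughly 11 / 12 / 1858
ADD² respectively — calibration removes almost all of the error that using
the bare species constant incurs at the size extremes.

## Layout

```
src/entocalib/        library modules
src/entocalib/data/   species registry (CSV + JSON mirror), size-range survey
tests/                pytest suite (unit, property and acceptance tests)
scripts/acceptance.py coefficient reproduction script
docs/methods.md       model, assumptions, numerical choices, limitations
```
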