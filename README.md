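# tracedose

Preclinical radiotracer dosimetry in Python: from gamma-counter
biodistribution data to per-organ time-activity curves, bootstrap cumulated
activities, MIRD-formalism absorbed doses in the mouse, extrapolated human
organ doses, and tumor doubling-time metrics.

The package targets the standard small-animal workflow for targeted
radionuclide therapy (TRT) candidates such as iodine-131-labelled
melanin binders: cohorts of tumor-bearing mice receive a tracer injection,
groups are sacrificed at fixed timepoints (default 3 animals at 1, 3, 6, 24
and 72 h), organs are excised, weighed and counted, and the counting data are
turned into organ absorbed doses and a human dose projection.

## The model

Each organ's decay- and background-corrected uptake, expressed as percent of
injected activity per gram (%IA/g), is fitted with a family chosen by organ
class:

| organ class | model | closed form |
|---|---|---|
| tumor | uptake–washout | y = a·(1 − e^(−bt))·e^(−ct) |
| eyes | uptake–physical decay | y = a·(1 − e^(−bt))·e^(−λt), λ = ln2/T½ fixed |
| other | bi-exponential | y = a·e^(−bt) + c·e^(−dt) |

Fits are robust nonlinear least squares (trust-region-reflective solver,
Tukey bisquare reweighting). The time-integrated activity coefficient is the
closed-form integral over [0, ∞); its 95% CI comes from a
leave-one-and-two-out resampling scheme (153 refits by default, 2.5/97.5
percentiles) matched to the serial-sacrifice design. Absorbed doses follow
the MIRD schema D(target) = Σ_source Ã(source)·S(source→target); murine
per-gram coefficients extrapolate to humans by relative organ-mass scaling.
Tumor growth uses the caliper volume V = L·S²/2 and the exponential doubling
time DT = ln2/a from a log-linear fit per animal.

## Worked example

```python
from tracedose import (simulate_biodistribution, default_config, samples_to_series,
                       bootstrap_tiac_ci, cumulated_activity_absolute, absorbed_dose,
                       fit_timeactivity)
from tracedose.io import read_svalue_table
from tracedose.pipeline import packaged_data_path

samples, truth = simulate_biodistribution(default_config(seed=7))
series = samples_to_series(samples)

fit = fit_timeactivity(series["tumor"], "uptake_washout")
print([round(p, 4) for p in fit.model.params])
# [31.526, 0.6663, 0.0082]   (a %IA/g, b h^-1, c h^-1)

ca = bootstrap_tiac_ci(series["tumor"], "uptake_washout", seed=7)
print(f"tumor TIAC = {ca.tiac:.3f} (95% CI {ca.ci_low:.3f}-{ca.ci_high:.3f}) IA.h/g")
# tumor TIAC = 37.801 (95% CI 32.160-61.604) IA.h/g

mouse = read_svalue_table(packaged_data_path("svalues_mouse_synthetic.tsv"),
                          packaged_data_path("masses_mouse_synthetic.tsv"), "mouse")
A = cumulated_activity_absolute(ca.tiac, mouse.mass("tumor"), 18.5)  # MBq
print(f"cumulated activity = {A:.1f} MBq.h; "
      f"tumor dose = {absorbed_dose({'tumor': A}, mouse, 'tumor'):.1f} Gy")
# cumulated activity = 279.7 MBq.h; tumor dose = 53.1 Gy
```

The fitted parameters sit close to the generator's tumor curve (a = 30.4,
b = 0.74, c = 0.0087, peaking near 6 h at ~28.5 %IA/g); the TIAC of ~38
IA·h/g times the 0.4 g tumor mass and the 18.5 MBq therapeutic injection
gives ~280 MBq·h of cumulated activity, and the synthetic self S-value of
0.19 Gy/(MBq·h) turns that into a ~53 Gy tumor deposit for this random draw.

The same chain runs from the shell:

```
tracedose simulate --seed 7 --out biodist.csv
tracedose integrate --biodist biodist.csv --seed 7 --out tiac.csv
tracedose dose --tiac tiac.csv \
    --svalues src/tracedose/data/svalues_mouse_synthetic.tsv \
    --masses  src/tracedose/data/masses_mouse_synthetic.tsv \
    --activity 18.5 --out dose.csv
tracedose report --out run/        # full pipeline incl. human extrapolation
```

Note that the shipped S-value and mass tables are *synthetic* fixtures at
physically plausible magnitudes (file headers say so); for real studies,
transcribe published murine S-factors and phantom values into the same TSV
schema.

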