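# Methods

## Scope and data model

The pipeline covers the quantitative chain of a small-animal radiotracer
dosimetry study: gamma-counting biodistribution measurements → per-organ
time-activity curves → time-integrated activity coefficients (TIACs) with
bootstrap confidence intervals → MIRD absorbed doses in the mouse → a human
organ-dose projection → tumor growth metrics. Time is in hours throughout;
uptake is stored as percent injected activity per gram (%IA/g, so 28.5 means
28.5%); TIACs are fraction-IA·h/g; S-values are Gy/(MBq·h); human dose
tables report Gy/GBq.

## Counting corrections

A raw measurement is `(counts − background) × calibration × e^(+λt)`:
background is subtracted first (it is a property of the counting room and
does not decay with the sample), then the net count rate is calibrated to
MBq and decay-corrected to injection time so %IA/g reflects tracer biology
rather than radionuclide decay. Negative net counts clip to zero with a
warning. The iodine-131 half-life defaults to 192.6 h (8.02 d) and is
configurable; the physical decay constant is λ = ln2/T½ exactly.

## Time-activity models

Three closed-form families, assigned by organ class:

* tumor — uptake–washout `a(1−e^(−bt))e^(−ct)`;
* eyes — uptake with physical decay only, `a(1−e^(−bt))e^(−λt)`. λ is
  *fixed* at the physical decay constant, not fitted: the defining formula
  ties the terminal slope to the radionuclide, reflecting effectively
  irreversible melanin binding in pigmented ocular tissue. Treating λ as
  fixed (rather than a free rate) is an explicit modelling assumption.
* every other organ — bi-exponential `a·e^(−bt) + c·e^(−dt)`.

All amplitudes are bounded at ≥ 0 and all rates at > 0 by box constraints in
the solver (no transformation), so every fitted curve is nonnegative and
integrable.

### Fitting

Nonlinear least squares with scipy's trust-region-reflective solver
(xtol = ftol = gtol = 10⁻¹²), wrapped in iteratively reweighted least squares
with Tukey bisquare weights, tuning constant 4.685 (95% Gaussian
efficiency), residual scale 1.4826·MAD, at most 100 outer iterations,
relative parameter tolerance 10⁻⁸. When residuals are numerically zero the
loop exits with unit weights, which makes noise-free fits exact rather than
0/0-unstable. Robust mode can be disabled; weights are then identically 1.

Initial values are deterministic and data-driven: amplitudes from the
maximum observed %IA/g, the bi-exponential slow rate from a log-linear fit
of the last two timepoint means, the fast component by curve peeling of the
first two, and the uptake rate b starting at 1 h⁻¹. Inputs are canonically
sorted before fitting, so the result is invariant to point ordering, and
bi-exponential components are reported fast-first. A bi-exponential whose
two rates coincide within 10⁻⁶ relative is collapsed to a mono-exponential
with amplitude a+c and flagged degenerate instead of reporting an
unidentifiable split.

Fits use all per-animal points, not per-timepoint means: the resampling
scheme below removes individual animals, which requires the per-animal
residual structure to be preserved.

## TIAC and its confidence interval

The TIAC is the closed-form integral over [0, ∞) divided by 100:
`a/b + c/d` for the bi-exponential and `a·b/(c(b+c))` for the uptake
families (c the washout or physical rate). No partial trapezoid over the
observed range is added — the fitted families vanish at infinity and the
rate floor guarantees convergence. The numerical oracle integrates the same
curve by adaptive quadrature, panel-wise at the model's characteristic time
scales (1/r, 10/r, 40/r per rate) with a default infinite upper limit;
truncating at a finite horizon is *not* equivalent at 10⁻⁶ precision — a
0.003 h⁻¹ component still holds e⁻⁶ ≈ 0.25% of its integral beyond 2000 h.

Uncertainty follows the serial-sacrifice design, in which the animal within
a timepoint is the exchangeable unit: each resample independently removes
one (leave-one-out) or two (leave-two-out) randomly chosen animals from
every timepoint, refits and re-integrates; the default `combined` scheme
alternates the two depths, 153 resamples in total, and the 95% CI is the
uncorrected 2.5/97.5 percentile interval. The point estimate is the
full-data fit, not the resample mean. Resamples whose reduced data cannot be
fitted are skipped and counted; more than 50% skips flags the interval
unreliable. Whether the original 153-fit scheme enumerated the leave-out
combinations exhaustively is not reconstructible; resamples are drawn
randomly here and 153 is a plain configurable count. Alternating the two
leave-out depths matters for calibration: leave-one-out subsets alone vary
too little (intervals under-cover, roughly 84% in the mean approximation)
while leave-two-out alone over-covers; the mixture lands the empirical
coverage in the low-to-mid 90s at the default design (measured 91.6% over
500 simulated studies at 5% noise).

## Doses

Cumulated activity inverts the per-gram normalization:
Ã = TIAC × organ mass × injected activity (MBq·h). The MIRD sum
D(target) = Σ_source Ã(source)·S(source→target) runs in two modes:
`self` (source = target only, the default) and `cross` (full sum, erroring
on any missing S pair by name). Published preclinical reports rarely state
whether cross-organ contributions were included, so the mode is explicit
config recorded in report provenance; with nonnegative S-values self mode is
always a lower bound on cross mode.

Human extrapolation defaults to relative-mass scaling,
`tiac_human(organ) = tiac_mouse/g × m_organ,human × (M_mouse/M_human)`,
i.e. the fraction of injected activity per gram of tissue is assumed to
scale with the inverse of total-body mass; a `direct` strategy carries the
mouse per-organ TIAC over unchanged. The strategy is recorded in provenance
because no single convention is universal. Dose tables append a total-body
row (summed cumulated activity against the total-body self S-value), report
dose per unit activity (Gy/MBq mouse, Gy/GBq human) and dose at the stated
activity, with the product identity exact by construction.

The shipped S-value and organ-mass tables are synthetic fixtures: self-dose
terms at first-principles magnitude (≈1.1×10⁻⁴ J per MBq·h from the mean
iodine-131 beta energy, divided by organ mass, times an absorbed fraction of
0.7 mouse / 0.9 human). They make the pipeline runnable and hand-checkable
but are not published values; the TSV schema doubles as the template for
transcribing real murine and phantom S-factors. The packaged human
dose-coefficient table, by contrast, contains published per-GBq coefficients
for the iodine-131 melanin tracer and is used as *input* when verifying the
dose-at-activity arithmetic.

## Tumor growth

Caliper volume V = L·S²/2 (mm³). Growth is exponential N = N0·e^(at), fitted
per animal by ordinary least squares on log-volume — deterministic and
standard, rather than a nonlinear fit on the volume scale; DT = ln2/a so
DT·a = ln2 identically. Observations with zero volume (pre-palpable) are
excluded with a count; a nonpositive slope yields DT = ∞ and a shrinking
flag rather than an error. Group summaries report median and mean DT;
inferential testing is out of scope. (Published doubling times are sometimes
printed with the unit "days⁻¹"; DT here is in days — the rate a is the
quantity in days⁻¹.)

## Synthetic data generator

The biodistribution generator emulates the study conditions end to end:
3 animals per timepoint at 1, 3, 6, 24, 72 h, 0.37 MBq injected, organ
ground-truth curves of the three families, conversion to absolute activity,
physical decay to the sacrifice time, median-preserving multiplicative
lognormal noise (σ² = ln(1+cv²), default cv 0.15 — organ-to-organ biological
variability dominates counting statistics at these activities), conversion
to counter units (10⁻⁶ MBq/count), a 100-count background, and Poisson
quantization of the expected counts. With noise, background and quantization
disabled the corrections invert the generator exactly, which anchors the
round-trip tests. The default tumor curve (a = 30.4 %IA/g, b = 0.74 h⁻¹,
c = 0.0087 h⁻¹) peaks near 6 h at ≈28.5 %IA/g and retains ≈16 %IA/g at
72 h — a calibration of the fixture to a realistic melanin-tracer shape, not
a claim about any real dataset.

What the generator does *not* emulate: organ-coupled pharmacokinetics (each
organ's truth curve is independent, so no mass balance across organs),
animal-level random effects shared across organs, counter dead-time or
geometry effects, and any imaging. Passing tests therefore demonstrate
correctness of the estimation chain under the stated noise model, not
robustness to every artifact of real counting data.

The growth generator produces volumes N0·e^((ln2/DT)·day) × lognormal noise
on days 0–21 (3-day grid), back-converted to (L, S) pairs at fixed aspect
ratio 1.3 so the volume formula round-trips exactly; the default cohorts
contrast DT = 5 vs 26 days, 14 animals per arm, cv 0.10 — the magnitude of a
strong TRT growth-delay effect.

## Verification problem sizes

The self-checks in `scripts/acceptance.py` (and the mirror tests) use: 3000
random models for closed-form vs quadrature agreement (max relative error
~4×10⁻¹⁵); 200 repeats per family for parameter recovery at cv 0.05 (median
per-parameter relative errors ≤ 6%; the frozen test bounds of 10–15% are
roughly twice the Monte-Carlo-observed medians); 500 repeats × 153 resamples
for CI coverage (robust reweighting off in these sweeps — the lognormal
noise model generates no gross outliers, and the plain solver isolates the
resampling properties being measured); 200 repeats of the full
simulate→fit→integrate→dose chain (worst per-organ median dose error ≈3.5%
against a 15% bound); 200 repeats of the 14-vs-14 growth contrast (median
DT ratio ≈5.2 against truth 26/5 = 5.2). These sizes were chosen to estimate
each quantity to well under its acceptance margin.

## Known limitations

* The fitted %IA/g curves are decay-corrected, so their integrals are
  biological residence quantities; dose conversion assumes the S-value
  formalism absorbs the physical-decay bookkeeping (the eye family is the
  one place physical decay enters a curve explicitly).
* Percentile intervals are uncorrected; no BCa or bias correction.
* No cross-organ S fixtures ship, so `cross` mode requires user tables.
* Human extrapolation strategies are simple mass scalings; no
  allometric-time (kinetic) scaling is implemented.
* No bone-marrow dosimetry beyond a tabulated S entry, no voxel or Monte
  Carlo transport, no radiobiological (BED/EQD2) conversions.
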