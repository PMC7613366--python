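# Methods

This note documents the models, defaults and numerical choices behind
`vitispec`, and what the synthetic experiment does and does not
establish about real vineyard data.

## The estimation problem

Leaf reflectance R(λ) over 350–2500 nm responds to pigment content
(visible, 350–700 nm), chlorophyll status (red edge, 680–750 nm),
internal structure (NIR, 700–1300 nm) and water content (MIR,
1300–2500 nm). Heavy-metal stress perturbs all four, so a metal's leaf
concentration can be regressed on spectral features. The package
estimates, per metal, a mapping from either the full 2151-channel
spectrum or 32 derived spectral indices to concentration in mg/kg dry
weight, using a feature-selection step (PLS1) followed by a small
regression model (forward MLR or ε-SVR).

Region intervals are closed at both ends and overlap (RDE straddles the
VIS/NIR boundary). Where a unique assignment is needed — e.g. tallying
selected wavelengths per region — precedence RDE > VIS > NIR > MIR
applies: the red edge is the diagnostically distinctive region, so a
boundary channel counts as red-edge first.

## Synthetic stress experiment

No public spectral library exists for this design, so the generator is
a first-class module: every downstream stage is exercised against data
whose ground truth is known.

**Design.** Five metals at dose levels 1–4 × MAL (the irrigation-water
maximum allowed level), four replicate pots per metal×level cell, and a
control group. The arithmetic 5 treatments × 5 metals × 4 replicates
would give 100 pots; the published total of 84 is only consistent with
a single control group shared across metals (4 + 5·4·4 = 84), which is
what the generator does by default (`control_shared=False` restores
per-metal controls). Five leaves per pot give 420 leaf spectra. MAL
defaults are Cu 200, Zn 2000, Pb 100, Cd 10 µg/L; no standard value is
bundled for Cr, and `default_design(cr_mal_ugL=...)` defaults it to
100 µg/L (a common irrigation limit) as an explicit package choice.

**Reflectance model.** The healthy baseline is parametric: a 0.045
floor, a Gaussian green peak at 550 nm (amplitude 0.10, σ 35 nm), a
logistic red edge centred at 718 nm rising 0.41 to the NIR plateau, a
linear MIR decline (1.2×10⁻⁴ per nm beyond 1300 nm) and Gaussian water
dips at 1450/1940 nm (0.17/0.26, σ 40/55 nm). Stress adds, per dose
unit, a broadband lift (default 0.006) and Gaussian bumps (default
amplitude 0.012, σ 10 nm) at metal-specific sensitive band centres
(e.g. 1373, 631, 744, 438 nm for Cd). Bump gains get per-pot,
per-band lognormal jitter (CV 0.25, mean 1) so the bands are not a
single rank-one dose direction — real uptake varies between plants and
pathways, and a rank-one response would make multi-component variable
selection degenerate by construction. Both terms are non-negative, so
stressed mean reflectance dominates the healthy baseline channel-wise,
reproducing the qualitative healthy-vs-stressed contrast the analysis
expects.

**Noise.** Leaf-level spectral noise is white noise smoothed along
wavelength (Gaussian, 30 nm correlation length, SD 0.006) — instrument
and leaf-placement effects are spectrally smooth — plus extra white
noise (SD 0.012) below 400 nm, mimicking the noisy UV-blue window.
Reflectance is clipped to [0, 1].

**Concentrations.** Measured concentration for metal *m* in a pot with
dose *d* (0 unless the pot's treatment metal is *m*) is
`(baseline_m + slope_m · d) · LogNormal(CV 0.20)`. Every metal is
assayed in every pot (long-format table), so each metal's regression
uses all 84 pots — most observations sit near the baseline, as in real
dosing studies where only one treatment group is enriched. Defaults
(baseline, slope in mg/kg DW): Cu 8/20, Zn 30/60, Pb 2/18, Cr 1.5/5,
Cd 0.3/4 — ordinary foliar ranges with clear dose separation. Values
below the instrument detection limits (Zn 0.008, Cu 0.025, Pb 0.01,
Cr 0.04, Cd 0.009 mg/kg) are reported at the limit and flagged
censored, the standard left-censoring convention. Lognormal noise is
used because concentrations are positive and right-skewed.

All randomness flows from one integer seed; identical seeds give
bit-identical datasets.

**What the generator does not emulate.** No radiative-transfer leaf
optics (a PROSPECT-class model would couple bands physically), no
soil–plant transfer chemistry, no growth or phenology over the
seven-month stress period, no instrument detector-seam artefacts. Tests
passing on this generator show the *pipeline* is correct and that the
planted signal is recoverable under the stated conditions; they do not
show that real vine spectra carry equally recoverable signal.

## Preprocessing

Min–max scaling maps each variable to [0, 1] over its fitted range and
is exactly invertible, so test RMSE can be reported in mg/kg by
multiplying by the fitted range. Scalers are fitted on the training
split only and applied to the test split (test values may fall outside
[0, 1]); `scale_before_split=True` restores pooled scaling for
protocols that normalise before splitting, at the cost of mild
leakage. Constant variables scale to 0 with a warning rather than
dividing by zero.

The 70/30 split takes exactly `round(0.7·n)` training samples (59/25
at n = 84), allocated across treatment-level strata by largest
remainder and shuffled with a seeded generator. Strata smaller than two
fall back to an unstratified split with a warning.

## PLS1 and variable selection

NIPALS PLS1 with internal mean-centering of X and y (centering is a
NIPALS requirement regardless of prior 0–1 scaling). Deflation stops
early if the response is exhausted (‖X'y‖ < 10⁻¹³). Regression
coefficients use `b = W(P'W)⁻¹q`. Correctness is pinned by two
independent oracles in the test suite: brute-force projection onto the
Krylov subspace span{X'y, (X'X)X'y, …} and scikit-learn's
PLSRegression; at full rank the fit equals OLS.

The component count minimises 10-fold cross-validated RMSE over
1..k_max (default 10); exact ties resolve toward fewer components.
"Factor load" is read as the X-loading vector **p** (a config switch
allows the weight vector **w**, since the two are often conflated);
selection takes the max-|loading| variable per component in component
order, and a variable already selected yields that component's
runner-up, so selections are unique.

On realistic (broadband + noise) data after per-channel min–max
scaling, the selected wavelengths need not coincide with the planted
sensitive bands: scaling equalises every channel's range, so
dose-correlated broadband channels compete with the bands, and
components load on broad correlated regions. The planted-band recovery
demonstrated in the tests therefore uses the identifiable regime —
channel-localised effects (bump width ≪ channel spacing), high effect
size, low noise, no broadband lift — where attributing components to
individual channels is well posed. This mirrors practice: "the"
informative wavelength is only defined up to the width of the
underlying absorption feature.

## Regression models and diagnostics

**Forward MLR.** Starting from the intercept, the candidate with the
largest SSE reduction enters if its partial-F p-value is below
`alpha_enter` (default 0.05); exact collinearity with the current model
excludes a candidate. The final model is refit by least squares. Note
that screening the best of *k* candidates inflates the per-step entry
rate to roughly 1−(1−α)^k; callers wanting a familywise 5% should
divide α by the candidate count.

**Validity gates.** Durbin–Watson d (computed in dataset row order —
the data have no time axis, so row order is the declared convention)
must lie in [1.5, 2.5]; all VIFs (auxiliary regressions with
intercept) must be < 10; the overall F-test p-value must be < 0.05.
Failing models are reported with flags, never suppressed — an invalid
model is a finding, not an error. Models with fewer than two predictors
have no multicollinearity to measure and pass the VIF gate vacuously.

**ε-SVR.** Grid search over kernels {linear, RBF, polynomial, sigmoid},
cost {0.1, 1, 10, 100}, ε {0.01, 0.1}, γ {0.05, 0.1, 0.25, 0.5, 1},
degree 2–11, kernel coefficient {0, 1}, scored by v-fold CV RMSE
(seeded folds, ties keep grid order), winner refit on the full training
set. libsvm iterations are capped at 2×10⁵ because some
high-cost/low-ε polynomial configurations otherwise fail to terminate;
well-behaved fits converge far below the cap. A reduced
linear+RBF grid (`svr_grid="fast"`) is available for quick runs and is
used in most tests; the acceptance script uses the full grid.

**Metrics.** R² = 1 − SSE/SST and RMSE on train and test; RMSE is also
reported in mg/kg via the inverse concentration scaling (an exact
rescale). SST = 0 flags R² as undefined rather than raising.

## Pipeline and problem sizes

`run_experiment` composes everything per metal × feature track and
writes a deterministic report bundle (selection table, model table,
correlogram, group-mean spectra, pot spectra, concentrations, resolved
config; every CSV carries the seed and config hash in a header
comment). Modelling is at pot level (n = 84) by default — spectra are
averaged per pot before feature computation — with a leaf-level switch.
Descriptive outputs exclude censored concentrations pairwise when
correlating.

Problem sizes in the shipped tests and acceptance script are the
design's natural sizes (84 pots, 420 spectra, 2151 channels); the
recovery simulations use 100 seeded replicates of the single-metal
(20-pot) design, and test-only SVR runs use the reduced grid. These
choices keep the whole suite in the minutes range on one CPU while
exercising every stage at full spectral resolution.

## Known limitations

- The stress response is additive and monotone; antagonistic or
  saturating dose effects are not modelled.
- Censored concentrations enter regressions at the detection limit; no
  Tobit-style likelihood is attempted.
- The Durbin–Watson gate tests row-order autocorrelation only, which is
  a convention in the absence of a natural observation ordering.
- Selection reports one variable per component; correlated neighbour
  channels carry essentially the same information and the reported
  channel is representative, not unique.
- mNDVI705 defaults to the form with the (R750 + R705) numerator for
  protocol fidelity; the conventional difference form is available via
  a flag. SIPI's (R445 − R800)/(R680 − R800) equals the conventional
  (R800 − R445)/(R800 − R680) algebraically.
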