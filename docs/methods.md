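# Methods

## The problem

In school-aged children the eye grows. Part of that axial-length (AL) growth
is *physiological*: it is compensated by loss of crystalline-lens power (and,
to a lesser degree, anterior-chamber deepening) and leaves the refraction
unchanged. The remainder is myopic progression. Clinicians who monitor
children in orthokeratology cannot use refraction to separate the two —
corneal reshaping invalidates it — so they need the physiological component
estimated from structural data alone.

The package operationalizes the physiological component through a fitted
cross-sectional prediction surface

    AL = f(age, K_mean, CCT, WTW, SER, sex) + ε

for myopic children aged 6–18 with SER in [−8, 0] D. Holding refraction and
the corneal parameters fixed while advancing age traces out a growth curve
whose slope is the physiological elongation **rate**

    ∂AL_phy = ∂f/∂age   [mm/year]

and whose increment between two ages is the physiological elongation
**amount**

    ΔAL_phy(a1→a2) = f(a2) − f(a1) = ∫ ∂f/∂age da   [mm].

The identity between the difference form and the integral form is checked
numerically at every evaluation (composite Simpson with step ≤ 0.1 y,
agreement required to 1e-6 mm): it is the fundamental theorem of calculus,
so any violation indicates a defect in the derivative machinery, not a
scientific finding.

Key modelling assumptions, inherited from the cross-sectional design:

* K-mean, CCT and WTW are treated as age-stable over the school years;
* the surface describes population means, not individual trajectories;
* ACD is *excluded* as a model covariate: it drifts with age, which makes the
  design collinear with the age term and the fit unstable. ACD is still
  simulated and consumed by the lens-power stage.

## Feature maps and fitting methods

A `FeatureMap` is an ordered monomial basis over {age, sex, ser, k_mean,
cct, wtw} with exactly one intercept. Two presets ship:

* `main_effects` — intercept, age, sex, SER, K-mean. This is the form of the
  published reference regression for this population
  (AL = 40.31 + 0.056·age − 0.013·sex − 0.396·K − 0.353·SER), available as
  `reference_linear_model()`. Its elongation rate is the age coefficient,
  constant at 0.056 mm/year.
* `curved` — main effects plus age², age·ser, age·k_mean, age·sex. Only a
  basis with age curvature/interactions can produce the clinically observed
  behaviour of rates that fall with age and differ by SER, corneal power and
  sex. Published rate tables imply the production surfaces behind them carry
  such terms even when only a main-effects equation is printed; we make the
  basis explicit and configurable rather than guessing the original.

Six fitting methods share one contract (`ALGrowthModel(...).fit()` →
`ALGrowthResults`): OLS; bisquare IRLS; ε-insensitive linear SVR on
polynomial maps of degree 1/2/3; and bagged regression trees.

The robust fit is the de-facto standard IRLS with Tukey's biweight:
initialize at OLS; per iteration compute leverage-adjusted residuals
r/√(1−h), a MAD scale s = median|r_adj|/0.6745, standardized residuals
u = r_adj/(c·s) with tuning constant c = 4.685 (95% Gaussian efficiency),
bisquare weights w = (1−u²)² for |u| < 1 else 0, and refit by weighted least
squares; stop when the maximum coefficient change is below 1e-8 or after 50
iterations (non-convergence sets a flag rather than raising). A degenerate
scale (MAD ≈ 0, e.g. an exact fit) falls back to the OLS solution with a
warning. The implementation is cross-checked in the test suite against
statsmodels' `RLM` with the same norm (agreement ≈ 7e-4 on contaminated
cohorts; small differences stem from the leverage adjustment, which
statsmodels omits).

SVR hyperparameters default to ε = 0.1·SD(AL), C = 1, standardized inputs,
centred target; bagged trees to 30 trees with minimum leaf size 8. None of
these defaults are claimed to match any published configuration (none is
stated anywhere); they are reasonable midpoints recorded in the config.

## Validation harness

5-fold cross-validation assigns folds by seeded random permutation (sizes
differ by ≤ 1; 1011 records split 203/202/202/202/202). Every method sees the
same assignment. Metrics (R², Pearson R, RMSE, MAE, MSE) are computed on the
*pooled* out-of-fold prediction vector — one number per method, matching the
single-row-per-algorithm presentation of comparison tables; fold-level
metrics are available via `per_fold=True` for readers who prefer averages.

Subgroup accuracy tables stratify by SER {(−3, 0], (−6, −3], ≤ −6} (edges to
the more-myopic bin, so −3.00 D is in the middle stratum), K-mean {< 42,
[42, 44], > 44} (edges inclusive in the middle), and age {6–10, 11–14,
15–18} crossed with sex. Each row reports n, %, mean predicted and measured
AL, mean error with its t-based 95% CI, a paired t-test p-value, and an AL
interval computed as mean ± 1.96·SD of predicted AL — a *population range*
interval, chosen because subgroup AL intervals in clinical reports are far
too wide to be standard errors of the mean. Identical prediction/measurement
vectors give p = 1 by convention (zero-variance differences).

## The published rate grid and its reconstruction

A 96-cell published grid of ∂AL_phy (ages {6, 18} × SER {−1…−6} × K-mean
{40, 42, 44, 46} × sex, at CCT 550 μm and WTW 12 mm) ships as a
checksummed CSV fixture. `reconstruct_rate_model` fits a linear rate surface
to those cells by least squares; the default basis {1, age, ser, k_mean,
sex, age·k_mean} was chosen because the grid's age slopes vary with K while
its SER spacing is age-stable. The fit reproduces the grid's sex-by-age
marginal means (0.092/0.027 mm/year male at 6/18 y; 0.085/0.021 female) and
its extreme corners (0.116 and 0.003 mm/year) to within ±0.002 mm/year.

The maximum per-cell residual is 0.0047 mm/year, set by two cells in the
male rows at SER −3 whose printed values duplicate the neighbouring SER −4
column (e.g. K 42, age 6 prints 0.098 at both) — almost certainly a
typesetting artifact in the source table; every other cell is explained to
better than 0.002. The reconstruction quantifies, but cannot resolve, this
anomaly, so the residual is reported rather than hidden.

## Lens-power back-calculation

Crystalline lens power is inferred by paraxial vergence tracing through a
reduced schematic eye with the lens collapsed to a single principal plane at
depth ACD + c: refraction moved from the spectacle plane (vertex distance
12 mm by default, configurable to 0) to the cornea, corneal power added,
vergence propagated over the reduced distance (ACD + c)/n, and the lens
power read off as the difference from the vergence 1000·n/(AL − ACD − c)
required to focus on the retina. The named procedures differ only in their
constant sets: c ∈ {2.145, 2.221, 2.875} (modified Stenström) and {2.230,
2.306, 2.891} (Bennett–Rabbetts) for the Gullstrand–Emsley (n = 4/3),
Bennett–Rabbetts (n = 1.336) and customized eye models respectively. The
customized model keeps n = 1.336, since its c constants were derived within
the Bennett–Rabbetts framework. The "customized" c values are population
means used as inputs; no per-eye c estimation is attempted (no phakometry is
available). Two-constant formulations that scale c with lens thickness are
out of scope — only single lumped constants are published for these
procedures.

The forward problem (`forward_refraction`) is the exact algebraic inverse
and serves as the round-trip oracle: back-calculation recovers a forward-
traced lens power to ~1e-14 D over the full biometric range. Sign
conventions frozen after sweep oracles: lens power falls with AL and with
K-mean, and rises with myopia magnitude at fixed geometry.

Age-group summaries use strata {6–9, 10–12, 13–15, 16–18} on the integer
part of age, with a one-way ANOVA across groups as the trend test (p = 1 by
convention when all values are identical).

## Synthetic cohort generator

No per-eye dataset with cycloplegic refraction is publicly deposited for
this population, so the generator emulates the published cohort summary:
truncated-normal marginals (age 11.18 ± 2.49 y on [6, 18]; SER −3.21 ± 1.61 D
on [−8, 0]; K-mean 43.33 ± 1.44 D; CCT 553 ± 30 μm — the printed "± 0.03" is
read as 0.03 mm, a unit typo; WTW 11.98 ± 0.44 mm; ACD 3.33 ± 0.22 mm),
48.57% male, and AL = reference surface + N(0, 0.378 mm), the residual scale
set to the published cross-validated RMSE of the best model. Truncation is
by rejection; records are drawn one at a time from a single seeded stream so
record *i* is independent of cohort size; identical specs reproduce
identical cohorts bit for bit.

What the generator does **not** emulate: the joint distribution of
covariates. Only marginals are published, so covariates are independent by
default; two documented couplings (Gaussian-copula age–SER correlation,
default −0.3 when enabled; ACD–age slope, default +0.0085 mm/y when enabled)
are off by default. A consequence worth stating plainly: with independent
covariates the total AL variance is smaller than in clinical samples where
age, SER and corneal power correlate, so cross-validated R² on default
synthetic cohorts sits near 0.81 rather than the mid-0.80s-to-0.87 reported
for clinical data. Passing tests therefore demonstrate the correctness of
the machinery (recovery, calibration, invariances), not clinical
performance.

## Numerical choices and problem sizes

* Derivatives are analytic (monomial calculus); central finite differences
  (h = 0.01 y) appear only as cross-checks, never as the primary route.
* Linear models serialize coefficients as hexadecimal floats for bit-exact
  reload.
* Pipeline CSVs print 6 significant digits and embed a config hash;
  identical configs rerun byte-identically.
* Test and acceptance problem sizes (cohorts of 150–1011, 20 contamination
  replicates of n = 300, 1000 round-trip eyes, 40 randomized surfaces) were
  chosen to make every stochastic margin decisive at interactive runtimes.
* The robust-vs-OLS contamination comparison measures coefficient error in
  the design-weighted norm (RMS fitted-surface difference over the cohort)
  against the clean-data least-squares fit of the same cohort. The paired,
  design-weighted formulation isolates sensitivity to the injected outliers;
  raw intercept comparisons are instead dominated by extrapolation to
  K-mean = 0, forty diopters outside the data, where sampling noise common
  to both estimators swamps the contamination effect.

## Known limitations

* The true basis of the production surfaces behind published rate tables is
  unrecoverable; the `curved` preset and the grid reconstruction bracket it
  but do not claim to match it.
* Per-coefficient inference (standard errors, p-values for the reference
  equation) is not reimplemented; only the validation harness's paired tests
  and CIs are provided.
* The vergence procedure may differ from other published lens-power variants
  by a constant offset; no numeric agreement with any published cohort-mean
  lens power is claimed, and the synthetic cohort's mean (~22 D) should be
  read only as order-of-magnitude plausible.
* Cross-sectional surfaces say nothing about within-child longitudinal
  trajectories; no longitudinal simulation is attempted.
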