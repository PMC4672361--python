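# Methods

## Exposure and risk model

The package assesses lifetime carcinogenic risk from PAHs in drinking
water via two routes, ingestion and dermal contact, using the standard
US-EPA chronic-daily-intake formulation (see README for the equations).
Key modelling choices:

* **BaPeq as the dose metric.** All carcinogenic potency is expressed
  relative to benzo[a]pyrene through potency equivalency factors. The
  default PEF set (BaA 0.1, Chy 0.001, BaP 1, BbF 0.1, BkF 0.01, DahA 1,
  IcdP 0.1) is the US-EPA (1993) relative-potency scheme; it is fully
  overridable through the `pefs` config block for users who prefer other
  schemes.
* **Units.** Concentrations are ng/L at every file and API boundary and
  converted to mg/L exactly once, inside the dose equations. The
  lifetime averaging time is fixed at 70 years × 365 days = 25,550 days;
  the deterministic exposure duration is also 70 years, a deliberate
  upper-bound (risk-protective) choice.
* **Dermal slope factor.** The oral slope factor (7.3 (mg/kg/day)⁻¹ for
  BaP) is an administered-dose quantity; the dermal route works in
  absorbed dose, so the SF is divided by the 92% gastrointestinal
  absorption fraction. Computation keeps the unrounded value (7.9348…);
  presentation rounds to 7.9. A `use_rounded_dermal_sf` switch in
  `total_risk` reproduces tables that carry the rounded value through.
* **Kp for BaP (1.2 cm/h) is applied to BaPeq as a whole.** Permeability
  is compound-specific; using the index compound's value for the mixture
  is a recognised approximation that errs on the side of overestimating
  risk for the less permeable congeners.
* **Classification** uses the 10⁻⁶–10⁻⁴ risk-management band with strict
  inequalities on both edges (a risk of exactly 10⁻⁶ is still "below de
  minimis").

## Non-detect handling

Analytical non-detects carry no numeric value; a substitution policy
resolves them where a number is needed: `zero` (default for BaPeq and
PAH sums, so a fully-censored carcinogen contributes nothing), `half_dl`
(default for geometric means and group comparisons, since zero would
break the log transform) or `dl`. The three policies are ordered, and
results under them bracket the censoring uncertainty.

## Monte Carlo engine

Uncertain parameters are sampled independently — no dependence structure
is imposed — from per-parameter specs: Cw from a distribution fitted to
the detected BaPeq values (candidates fitted by maximum likelihood,
selected by AIC with a Kolmogorov–Smirnov tie-break), ED uniform on
0–70 years (zero-duration draws are legal and yield zero risk), and the
anthropometric parameters (BW, ET, IR, SA) lognormal around their point
values. Their coefficients of variation are rarely published; the
default is CV = 0.2 for each, configurable, and no conclusion shipped
with the package depends on these defaults — tests rely only on
orderings and degenerate limits. Lognormal specs are parameterized by
natural-scale mean and CV (µ = log m − σ²/2, σ² = log(1+CV²)).

Summaries use the empirical mean, SE = sd/√n and type-7
(linear-interpolation) quantiles, so P5/P50/P95 are deterministic given
the draws. Sensitivity is the Spearman rank correlation between each
varied input column and the output risk ("rank order correlation", the
convention of spreadsheet risk tools); constant inputs are reported as
NaN rather than zero. With 10,000 draws, a lognormal Cw (CV 1.5) and
uniform ED dominate: ρ(Cw) ≈ 0.77 > ρ(ED) ≈ 0.58, with BW weakly
negative — the canonical ordering for this model.

## Campaign statistics

Geometric means with 95% t-intervals on the log scale summarize the
lognormal concentration data. Normality after Box-Cox transformation is
checked with Anderson–Darling and Lilliefors-corrected KS tests. The
Box-Cox λ maximizes the profile log-likelihood on a fixed grid [−3, 3]
in steps of 0.01 (computed in closed form, vectorized over the grid;
λ = 0 is the natural log). Group comparisons report both one-way ANOVA
on Box-Cox-transformed values and the rank test (Wilcoxon rank-sum for
two groups, Kruskal–Wallis for three); the rank-test p-value is the
headline in rendered tables, since rank tests are insensitive to the
transformation choice. No multiple-testing correction is applied by
default, matching common practice in campaign tables; exceedance
percentages are count/total to one decimal. Exceedance uses strict `>`
against limits (standards phrased "less than L" make equality
compliant).

## Synthetic campaign generator

The generator defines the study conditions for all tests:

* **Design**: 20 villages per group × 3 water types × 2 seasons, one
  pooled record per cell, with uniform random missingness at rate 8/240
  (≈232 realized samples) — cells are missing at random because no
  campaign publishes which cells failed.
* **Concentrations**: per analyte, log C = baseline + summer shift +
  water-type shift (DG reference) + village effect + noise. The default
  parameters are calibrated by least squares on the log geometric means
  of a built-in 6-cell (season × water type) fixture table typical of a
  PAH-impacted river basin; the per-analyte log-SD is back-derived from
  the fixture's CI widths (t-interval, ≈39 samples/cell), with a shared
  between-village log-shift of SD 0.3 carved out of the total. This is a
  documented synthetic fixture, not a fidelity claim. DahA is generated
  at trace level (GM 0.2 ng/L) below its detection limit, so it is
  always censored — mirroring campaigns where it is never detected.
* **Censoring**: detection limits default to 1 ng/L (2–3-ring), 2 ng/L
  (4-ring) and 5 ng/L (5–6-ring analytes), inside the 1–5 ng/L range of
  typical GC/MS methods. Raising a limit can only increase non-detects.
* **Cancer registries**: within each group, incidence and mortality
  (per 100,000/yr) are lognormal with the configured means/SDs (risk
  group 397.47 ± 92.35 incidence, 313.44 ± 73.83 mortality; control
  134.89 ± 50.33 and 140.06 ± 71.73), coupled by a Gaussian copula on
  log-rates whose correlation is solved analytically so the
  natural-scale within-group Pearson r hits the target (default 0.78).
  Pooling the two groups inflates the observed r above the within-group
  target because the group means are far apart — the generator's
  recovery checks therefore measure r within one group.

What the generator does **not** emulate: spatial structure, demography,
temporal autocorrelation beyond the two-season design, between-analyte
correlation beyond the shared village effect, and measurement error.
Passing tests therefore demonstrate the correctness of the computational
pipeline under a realistic lognormal monitoring regime, not the field
behaviour of any specific river basin.

## Problem sizes and numerics

Default runs use 40 villages (~232 samples) and 10,000 Monte Carlo
draws; recovery checks use 10,000 draws for distribution fitting, 5,000
villages per group for correlation recovery, and ~10,000 samples for
season-effect regression. A full pipeline run takes well under a minute
on a single CPU. Degenerate inputs are defined behaviour: all-point
Monte Carlo reproduces the deterministic result with SE = 0; constant
samples are rejected by the distribution fitter and reported NaN by the
normality tests; single-value groups refuse a CI.

## Known limitations

* Independence of Monte Carlo inputs ignores plausible BW–SA dependence.
* The single Kp overstates dermal uptake of the heavier congeners.
* Exceedance screening treats each sample independently; no
  village-level clustering adjustment is applied to the percentages.
* The deterministic "mean risk" averages over samples; averaging over
  villages first gives slightly different numbers, and both groupings
  are available from the per-sample risk table.
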