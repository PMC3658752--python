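# Methods

This note records the models behind `standgrade`, the choices made where
the design was genuinely open, and what the synthetic tests do and do not
demonstrate about real survey data.

## Measurement model

A standing-tree acoustic tool times a hammer-induced stress wave between
two probes about a metre apart on the lower stem. One measurement is eight
hits; each raw elapsed time includes a constant transit through the metal
probe tips, which is deducted, and the ultrasonically measured distance is
corrected by the sensor-to-probe-tip offsets. The reading velocity is the
mean of the eight per-hit velocities `d/tᵢ` (averaging velocities rather
than dividing distance by the mean time; at the ~2% spreads the QC rule
admits, the two differ negligibly). The QC statistic is the range of the
middle four sorted corrected times over their mean, with a default 0.02
threshold — the instrument's actual internal rule is proprietary, so this
contract is a faithful abstraction of its published behaviour, not a
re-implementation. Probe-tip constants and offsets are configuration
values, not built-in hardware numbers.

Tree-level velocity is the mean of QC-passing readings at one probe depth
across the measured cardinal directions (south and east in the survey
design). Readings exist at 1.5 cm and 3 cm insertion depth; the two are
highly correlated (R² ≈ 0.91) with the 3 cm readings ~0.07 km/s faster,
and all downstream analysis uses the 3 cm depth.

The one-dimensional wave equation `MOE_D = ρV²` operates in SI units with
explicit converters; velocities are otherwise carried in km·s⁻¹ and MOE in
kN·mm⁻², which equals GPa.

## Tree stiffness regression

Ordinary least squares of tree-mean board MOE on centered V², centered
DBH, and their product. Centering means come from the fitting sample and
are stored on the model; prediction without centering means fails loudly,
because silently assuming means shifts every prediction. All terms are
retained regardless of significance. Diagnostics: R² is the squared
correlation of observed and predicted values, RMSE the root mean squared
residual, and the mean percentage error uses the *observed* MOE in the
denominator (the convention here; the alternative denominator changes the
value only in the third decimal at these noise levels).

The shipped preset carries the case-study coefficients
(10.680, 0.2362, −0.1252, −0.0649). **Caveat:** the survey never published
the centering means of its 39-tree fit. The preset approximates them from
the pooled per-class survey moments — mean V² as the mean of squared
velocities, `Σnᵢ(mᵢ²+sᵢ²)/N ≈ 20.269 (km/s)²`, and mean DBH
`≈ 19.229 cm` — and logs a warning whenever it is constructed. This is the
single most important reproducibility caveat in the package: preset
predictions (and everything downstream of them) inherit it.

## Grades and logistic pass models

MSR grade names `"<Fb>Fb-<E>E"` encode the bending-strength design value
(psi) and mean stiffness (Mpsi). Stiffness thresholds use the exact
conversion 1 psi = 6,894.757 Pa; strength thresholds use the round
lumber-standard convention 145 psi = 1 MPa, which reproduces the published
metric design-value tables (11.4/14.5/16.6 MPa) where the exact factor
does not (2400 psi × 0.0068948 = 16.55 → 16.5). Both thresholds are
rounded to one decimal for the threshold table; exact values are carried
alongside. A board passes a grade when it passed visual grading
(No. 2 & Better) and its static MOE meets the rounded stiffness threshold,
ties passing; only stiffness drives grading, strength being metadata.

Pass proportions are modelled per board with a Bernoulli logit on the
tree's MOE_est. Boards from the same tree are treated as independent — a
deliberate simplification matching the original analysis; within-tree
correlation would widen standard errors but not bias the curve. When the
slope's Wald p-value exceeds α (default 0.05) the model is refit
intercept-only (closed form: logit of the pass fraction). Complete
separation or a single-outcome sample yields a model flagged degenerate
and unusable rather than an exception mid-pipeline.

The preset intercept-only 1650Fb-1.5E coefficient is θ₁ = 2.2442, whose
inverse logit is 0.9042; the same survey's published pass-rate table
prints a flat 92.0% for that grade (logit(0.92) ≈ 2.442, suggesting a
digit transposition in one of the two published numbers). The package
ships both — computations use the coefficient; the printed figure is kept
as `presets.CONSTANT_GRADE_REPORTED_PCT` — and does not guess which is
canonical.

## Stand level

Prism tallies are expanded at `BAF·40,000/(π·DBH²)` stems/ha (the familiar
`80,000/(π·DBH²)` at basal area factor 2). Stratum MOE_est distributions
use the frequency-weight form of the weighted SD, `√(Σw(x−μ)²/Σw)`, since
expansion factors are stem counts, not precision weights. Normality of
MOE_est within strata is assumed for the integration, as in the original
analysis; a skew/kurtosis report is emitted but never gates computation.
Because published per-class summaries do not state whether their means are
expansion-weighted, the stand summary table reports both the arithmetic
and the weighted moments, labelled.

Class comparisons: one-way ANOVA plus Tukey HSD at α = 0.05. The compact
letter display is derived from maximal cliques of the
"not-significantly-different" graph, ordered by descending clique-best
mean, so strata share a letter exactly when no pairwise test separates
them.

## Pass-rate integration

The stand pass rate is the integral of the normal MOE_est density times
the logistic pass curve. Default bounds are μ ± 8σ with the truncated
density renormalized, making the result a true conditional probability;
the literal published formulation integrates over the observed MOE_est
range *without* renormalizing, which is not a probability, and remains
available via explicit bounds with `renormalize=False` for fidelity runs.
Quadrature is adaptive (absolute tolerance 1e−9) with a 501-node composite
Simpson + Richardson fallback if the adaptive routine reports trouble. A
seeded Monte Carlo estimator (default 10⁶ draws; mean pass probability
over normal draws, standard error √(var/n)) serves as an independent
oracle in tests and verification reports, never as the primary estimator.
Regional regrouping pools strata as a stems-per-hectare-weighted normal
mixture, so each pooled rate is exactly the weight-convex combination of
component rates — asserted as a property test.

**Why published pass-rate tables are not reproduced exactly.** The
published stand rates depend on the per-hectare-weighted μ/σ of the raw
333-tree data, which were never printed. Evaluating the integral with the
published *unweighted* class moments and preset coefficients gives
systematically different values (e.g. ≈ 0.654 vs the printed 0.711 for
the 100–149-year stratum at 2100Fb-1.8E, and 0.904 vs 92.0 for the
intercept-only grade). The package therefore validates this stage by
construction — cross-method agreement, closed-form limits, end-to-end
recovery on synthetic data, and the qualitative regional ordering (the
50–149-year group beats the >150 group at the two higher grades, which it
does: 65.4 vs 56.9 and 37.1 vs 20.8 percent under the published moments) —
rather than by matching printed tables.

## Synthetic-data generator

The generator emulates the survey's statistical skeleton with these
defaults, chosen once:

| parameter | default | basis |
|---|---|---|
| class sizes | 75/79/79/100 (333) | survey design |
| velocity, DBH moments | per-class survey values | survey summaries |
| velocity–DBH correlation | 0 | none reported; configurable because pass rates are sensitive to it |
| DBH floor | 9 cm | smallest prism-countable stems |
| depth-pair offset | 0.07 km/s | published depth means 4.39 − 4.32 |
| depth-pair noise SD | 0.12 km/s | calibrated so the squared depth-pair correlation ≈ 0.91 at the pooled velocity variance (τ = σ_v·√(1/0.91 − 1)) |
| tree MOE residual SD | 1.06 kN/mm² | published regression RMSE |
| boards per tree | 2 | 77 boards over 39 trees |
| board-within-tree SD | 1.0 kN/mm² | not published; a realistic board-level scatter for small-dimension spruce lumber, deliberately a free parameter |
| visual-pass probability | 1.0 | all mechanically tested boards had passed visual grading |
| plots | 5 trees per plot → 67 plots | survey design |
| destructive subsample | 39, one per distinct plot | survey design |

Each class draws (velocity, DBH) from a bivariate normal with rejection
below the DBH floor; the depth-1.5 velocity is depth-3 minus the offset
plus noise; each sampled tree gets a latent mean MOE (regression
prediction plus residual), and boards scatter around it, floored at a
small positive minimum. One top-level seed feeds fixed per-stage
sub-streams, so any stage is independently reproducible and the whole
output is bit-identical for a given seed and config.

What the generator does *not* emulate: spatial plot geometry, growth and
mortality, knots and decay, moisture gradients, or any non-normality of
real MOE_est beyond what the regression's interaction term induces.
Passing tests therefore demonstrate internal consistency of the chain
under the stated stochastic model, not field validity of the preset
coefficients.

A noteworthy measured fact: because the interaction term makes MOE_est a
product of correlated quantities, the generated MOE_est distribution is
mildly right-skewed (skewness ≈ 0.8 at default moments), so the normal
assumption of the integration stage is itself an approximation — the
end-to-end test shows the integrated rate still tracks the empirical board
pass fraction to within ~1 percentage point at n = 20,000 boards.

## Numerical and edge-case choices

- Quadrature tolerance 1e−9 absolute/relative, 200-subinterval limit;
  Simpson fallback as above.
- Logistic evaluation uses the numerically stable `expit`; η of ±∞ (from
  degenerate all-pass/all-fail fits) maps to probability 1/0.
- Grade pass flags are monotone across nested thresholds by construction.
- Empty strata, single-tree strata, zero total weight, non-positive σ,
  malformed grade names, missing centering means, and ungraded boards all
  raise `ValueError` with a specific message; pipeline stages wrap causes
  in `PipelineError` with a distinct exit code per stage.
- CSVs are written with `%.17g` floats and read with round-trip float
  parsing, so record round-trips are bit-exact.

## Problem sizes used in the test suite

Simulation-based tests use 10,000 trees (coefficient recovery, end-to-end
pass-rate consistency, moment convergence), 20,000 boards for logistic
recovery, 10⁶ Monte Carlo draws for the quadrature cross-check grid, and
25 replicates for the stochastic Tukey-letter direction check. These sizes
give 3-SE assertions comfortable resolution while keeping the suite fast.

## Known limitations

- Preset centering means are reconstructed, not published (above).
- Board-level independence ignores within-tree correlation.
- The visual-grade flag is a single Bernoulli bit; there is no visual
  grading rule engine, strength (MOR) modelling, or moisture adjustment.
- The >200-year stratum's open upper bound and the two-group regional
  split follow the published stratification; no fire-history inference or
  mapping is attempted.
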