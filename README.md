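# standgrade

Standing-tree acoustic assessment of machine stress-rated (MSR) lumber
potential for boreal conifer stands.

Forest planners want to know, before harvesting, what fraction of a stand's
sawn output would meet the stiffness requirements of MSR grades such as
1650Fb-1.5E, 2100Fb-1.8E, or 2400Fb-2.0E. `standgrade` implements the full
assessment chain for time-of-flight acoustic surveys of standing trees:

1. **Acoustics** — eight-hit stress-wave measurements reduced to a tree
   velocity (probe-tip and sensor-offset corrections, middle-four QC rule),
   with the one-dimensional wave equation `V = √(MOE_D/ρ)` linking velocity
   to dynamic stiffness.
2. **Tree stiffness model** — a centered linear regression predicting the
   tree-mean static MOE of boards from the squared acoustic velocity and
   stem diameter:

   `MOE_est = β₀ + β₁(V² − m_V²) + β₂(DBH − m_DBH) + β₃(V² − m_V²)(DBH − m_DBH)`

   so β₀ is the predicted stiffness of an average tree. A case-study preset
   ships with coefficients (10.680, 0.2362, −0.1252, −0.0649), units
   kN·mm⁻² ≡ GPa.
3. **Grade models** — NLGA SPS-2 grade arithmetic (grade names encode Fb in
   psi and E in Mpsi; metric thresholds derived and rounded to one decimal),
   board grading by static MOE, and per-grade logistic pass curves
   `P(pass) = logit⁻¹(θ₁ + θ₂·MOE_est)` with automatic intercept-only
   fallback when the slope is not significant.
4. **Stand level** — variable-radius (prism) plot expansion
   `80,000/(π·DBH²)` stems/ha at basal area factor 2, expansion-weighted
   normal MOE_est distributions per time-since-fire (TSF) stratum, one-way
   ANOVA with Tukey HSD letter codes, and the pass-rate integral

   `pass rate = ∫ N(x; μ, σ) · logit⁻¹(θ₁ + θ₂x) dx`

   evaluated by adaptive quadrature with a seeded Monte Carlo oracle as an
   independent cross-check, plus stems-weighted regional mixtures.

A seeded synthetic-data generator reproduces the survey structure the
presets were calibrated to (333 trees in four TSF strata and 67 prism
plots, a 39-tree destructive subsample, two boards per tree), so the entire
chain is testable without the original field data.

## Worked example

Integrate the preset logistic grade models against per-stratum normal
MOE_est distributions taken at the case-study class moments:

```python
from standgrade import StandDistribution, preset_grade_models
from standgrade.pass_rate import pass_rate_table, regional_pass_rate
from standgrade.presets import SURVEY_CLASSES

dists = {
    c.label: StandDistribution(
        c.label, c.moe_est_mean, c.moe_est_sd,
        c.moe_est_mean - 4 * c.moe_est_sd, c.moe_est_mean + 4 * c.moe_est_sd,
        float(c.n), c.n)
    for c in SURVEY_CLASSES
}
models = preset_grade_models()
print(pass_rate_table(dists, models))
```

prints

```
           1650Fb-1.5E  2100Fb-1.8E  2400Fb-2.0E
tsf_class
50-99             90.4         65.4         38.2
100-149           90.4         65.4         36.1
150-199           90.4         57.1         24.3
>200              90.4         56.7         18.0
```

Each cell is the expected percentage of boards from that stratum meeting
the grade's stiffness requirement. The 1650Fb-1.5E column is constant
because its preset model is intercept-only (tree stiffness did not
significantly influence that grade's pass proportion). Rates fall from the
weakest to the strictest grade within every stratum, and the older strata
(>150 years since fire) lose the most at the top grades. Pooling strata
into two regional groups with stems-per-hectare weights:

```python
out = regional_pass_rate(
    dists, models["2400Fb-2.0E"],
    {"50-149": ["50-99", "100-149"], ">150": ["150-199", ">200"]})
print({k: round(100 * v.pass_rate, 1) for k, v in out.items()})
# {'50-149': 37.1, '>150': 20.8}
```

— younger, fire-regenerated stands are the better supply source for the
strictest MSR grade. (These figures use unweighted published class moments;
the per-hectare-weighted moments of the original raw data were never
published, so exact published pass-rate tables are not reproducible — see
`docs/methods.md`.)

The command line mirrors the library: `standgrade simulate`, `velocities`,
`fit-moe`, `grade`, `fit-grades`, `stand`, `pass-rates`, `run`, `verify`
(see `standgrade --help`).

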