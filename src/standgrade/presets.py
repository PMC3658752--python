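"""Case-study reference values for boreal black spruce acoustic grading.

These constants summarise a North Shore (Quebec) black spruce field survey:
333 standing trees measured acoustically in 67 variable-radius plots,
stratified by time since the last stand-initiating fire (TSF), with a
39-tree destructive subsample sawn into 77 boards for static bending tests.
They seed the synthetic-data generator and ship as presets for the tree-MOE
regression and the per-grade logistic pass models, so the full pipeline can
run without access to the (non-public) raw data.

Units: velocities in km·s⁻¹, DBH in cm, MOE in kN·mm⁻² (≡ GPa).
"""

from __future__ import annotations

from typing import NamedTuple


class ClassStats(NamedTuple):
    """Per-TSF-class survey summary (tree-level means and SDs)."""

    label: str
    n: int
    velocity_mean: float
    velocity_sd: float
    moe_est_mean: float
    moe_est_sd: float
    dbh_mean: float
    dbh_sd: float


#: Survey summaries per TSF class (years since fire), n = 333 total.
SURVEY_CLASSES: tuple[ClassStats, ...] = (
    ClassStats("50-99", 75, 4.48, 0.35, 11.16, 1.61, 15.36, 2.73),
    ClassStats("100-149", 79, 4.66, 0.35, 11.12, 1.45, 19.65, 5.16),
    ClassStats("150-199", 79, 4.40, 0.43, 10.61, 1.39, 20.53, 5.22),
    ClassStats(">200", 100, 4.42, 0.35, 10.55, 1.05, 20.77, 5.26),
)

#: Centered tree-MOE regression coefficients (intercept; centered V²;
#: centered DBH; interaction), fitted on the 39 destructively tested trees.
MOE_COEFFICIENTS: tuple[float, float, float, float] = (10.680, 0.2362, -0.1252, -0.0649)

#: Fit diagnostics reported for the regression above.
MOE_R2 = 0.41
MOE_RMSE = 1.06  # kN·mm⁻²
MOE_E_PCT = 0.01  # mean percentage error

#: Probe-depth pair: readings at 3 cm run ~0.07 km/s faster than at 1.5 cm,
#: with squared correlation 0.91 between the two depths.
DEPTH_PAIR_MEAN_30 = 4.39
DEPTH_PAIR_MEAN_15 = 4.32
DEPTH_PAIR_OFFSET = DEPTH_PAIR_MEAN_30 - DEPTH_PAIR_MEAN_15  # 0.07 km/s
DEPTH_PAIR_R_SQUARED = 0.91

#: The three MSR grades assessed, NLGA SPS-2 naming.
GRADE_NAMES: tuple[str, ...] = ("1650Fb-1.5E", "2100Fb-1.8E", "2400Fb-2.0E")

#: Logistic pass-model coefficients per grade: (theta1, theta2); theta2 None
#: means the tree-MOE predictor was not significant and the model is
#: intercept-only.
LOGISTIC_PRESETS: dict[str, tuple[float, float | None]] = {
    "1650Fb-1.5E": (2.2442, None),
    "2100Fb-1.8E": (-9.6062, 0.9413),
    "2400Fb-2.0E": (-31.2750, 2.6765),
}

#: The survey reports a flat 92.0% pass rate for the intercept-only grade
#: across all strata, yet invlogit(2.2442) = 0.9042.  (logit(0.92) ≈ 2.442,
#: suggesting a digit transposition somewhere in the published numbers.)
#: Both values are shipped; computations use the coefficient, and this
#: constant records the printed figure.  See docs/methods.md.
CONSTANT_GRADE_REPORTED_PCT = 92.0

#: Survey design constants.
N_TREES = 333
N_PLOTS = 67
N_DESTRUCTIVE = 39
N_BOARDS = 77
BASAL_AREA_FACTOR = 2.0  # m²·ha⁻¹ prism factor


def pooled_velocity_sq_mean(classes: tuple[ClassStats, ...] = SURVEY_CLASSES) -> float:
    """Pooled mean of squared velocity, E[V²] = Σnᵢ(mᵢ² + sᵢ²)/N."""
    n_tot = sum(c.n for c in classes)
    return sum(c.n * (c.velocity_mean**2 + c.velocity_sd**2) for c in classes) / n_tot


def pooled_dbh_mean(classes: tuple[ClassStats, ...] = SURVEY_CLASSES) -> float:
    """Pooled mean DBH, Σnᵢmᵢ/N."""
    n_tot = sum(c.n for c in classes)
    return sum(c.n * c.dbh_mean for c in classes) / n_tot


def pooled_velocity_variance(classes: tuple[ClassStats, ...] = SURVEY_CLASSES) -> float:
    """Pooled (within + between class) variance of depth-3 velocity."""
    n_tot = sum(c.n for c in classes)
    mean = sum(c.n * c.velocity_mean for c in classes) / n_tot
    return pooled_velocity_sq_mean(classes) - mean**2
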