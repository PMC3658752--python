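"""Centered linear regression predicting tree-mean static MOE.

The model regresses the tree-level mean static MOE of sawn boards on the
squared standing-tree acoustic velocity, the diameter at breast height, and
their interaction, with both explanatory variables centered on their sample
means:

    MOE_est = β₀ + β₁·(V² − m_v2) + β₂·(DBH − m_d) + β₃·(V² − m_v2)(DBH − m_d)

Centering reduces collinearity between the main effects and the interaction
and makes β₀ interpretable as the predicted MOE of an average tree.  The
centering means are part of the model: applying coefficients without the
means they were fitted against silently shifts every prediction, so the API
refuses to predict without them.

A preset model ships with the case-study coefficients
(10.680, 0.2362, −0.1252, −0.0649).  The survey never published its
centering means; the preset approximates them from the pooled per-class
survey moments and warns on construction (see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from . import presets

logger = logging.getLogger(__name__)

_MIN_FIT_N = 5


@dataclass
class TreeRecord:
    """One standing tree with inventory and acoustic attributes.

    MOE values in kN·mm⁻² (GPa), velocities in km·s⁻¹, DBH in cm.
    """

    tree_id: str
    plot_id: str
    tsf_class: str
    dbh_cm: float
    velocity_kms_d30: float
    velocity_kms_d15: float | None = None
    moe_observed: float | None = None  # tree-level mean of board static MOE
    moe_est: float | None = None

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0:
            raise ValueError("DBH must be positive")
        if self.velocity_kms_d30 <= 0:
            raise ValueError("velocity must be positive")
        if self.velocity_kms_d15 is not None and self.velocity_kms_d15 <= 0:
            raise ValueError("velocity must be positive")


@dataclass(frozen=True)
class FitDiagnostics:
    r_squared: float
    rmse: float  # kN·mm⁻²
    e_pct: float  # mean percentage error, observed in the denominator


@dataclass(frozen=True)
class LinearMOEModel:
    """Coefficients plus centering means (and diagnostics when fitted)."""

    beta0: float
    beta1: float  # per (km/s)² of centered V²
    beta2: float  # per cm of centered DBH
    beta3: float  # interaction
    mean_v2: float | None  # centering mean of V², (km/s)²
    mean_dbh: float | None  # centering mean of DBH, cm
    diagnostics: FitDiagnostics | None = None
    stderr: tuple[float, float, float, float] | None = None
    provenance: str = "fitted"

    def require_centering(self) -> None:
        if self.mean_v2 is None or self.mean_dbh is None:
            raise ValueError(
                "model has no centering means; predictions would be shifted "
                "— supply the means the coefficients were centered on"
            )
        if not (math.isfinite(self.mean_v2) and math.isfinite(self.mean_dbh)):
            raise ValueError("centering means must be finite")

    def predict(self, velocity_kms: float, dbh_cm: float) -> float:
        """Predicted tree MOE (kN·mm⁻²) for a depth-3 velocity and DBH."""
        self.require_centering()
        v = velocity_kms**2 - self.mean_v2
        d = dbh_cm - self.mean_dbh
        return self.beta0 + self.beta1 * v + self.beta2 * d + self.beta3 * v * d


def preset_moe_model() -> LinearMOEModel:
    """The case-study regression with pooled-moment centering means.

    The centering means are an approximation reconstructed from the pooled
    survey class summaries (mean of squared velocities, not square of the
    mean), since the fitted 39-tree means were not published.  This is the
    single most important reproducibility caveat of the preset and is logged
    whenever the preset is built.
    """
    logger.warning(
        "preset tree-MOE model: centering means approximated from pooled "
        "survey class moments (mean V² = %.3f, mean DBH = %.3f); "
        "predictions carry this approximation",
        presets.pooled_velocity_sq_mean(),
        presets.pooled_dbh_mean(),
    )
    b0, b1, b2, b3 = presets.MOE_COEFFICIENTS
    return LinearMOEModel(
        beta0=b0,
        beta1=b1,
        beta2=b2,
        beta3=b3,
        mean_v2=presets.pooled_velocity_sq_mean(),
        mean_dbh=presets.pooled_dbh_mean(),
        diagnostics=FitDiagnostics(presets.MOE_R2, presets.MOE_RMSE, presets.MOE_E_PCT),
        provenance="preset",
    )


def _design(trees: Sequence[TreeRecord], mean_v2: float, mean_dbh: float) -> np.ndarray:
    v2 = np.array([t.velocity_kms_d30**2 for t in trees]) - mean_v2
    d = np.array([t.dbh_cm for t in trees]) - mean_dbh
    return np.column_stack([np.ones(len(trees)), v2, d, v2 * d])


def fit_moe_model(trees: Sequence[TreeRecord]) -> LinearMOEModel:
    """Ordinary least squares on centered V², centered DBH and their product.

    Centering means are taken from the fitting sample and stored on the
    model.  Raises on fewer than five trees with observed MOE or on a
    rank-deficient design (e.g. all trees identical).
    """
    fit_trees = [t for t in trees if t.moe_observed is not None]
    if len(fit_trees) < _MIN_FIT_N:
        raise ValueError(f"need at least {_MIN_FIT_N} trees with observed MOE")
    mean_v2 = float(np.mean([t.velocity_kms_d30**2 for t in fit_trees]))
    mean_dbh = float(np.mean([t.dbh_cm for t in fit_trees]))
    X = _design(fit_trees, mean_v2, mean_dbh)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design matrix: predictors are collinear")
    y = np.array([t.moe_observed for t in fit_trees], dtype=float)
    res = sm.OLS(y, X).fit()
    model = LinearMOEModel(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        beta2=float(res.params[2]),
        beta3=float(res.params[3]),
        mean_v2=mean_v2,
        mean_dbh=mean_dbh,
        stderr=tuple(float(s) for s in res.bse),
        provenance="fitted",
    )
    diags = model_diagnostics(model, fit_trees)
    return LinearMOEModel(**{**model.__dict__, "diagnostics": diags})


def predict_moe(model: LinearMOEModel, tree: TreeRecord) -> float:
    """Predict and attach MOE_est for one tree."""
    tree.moe_est = model.predict(tree.velocity_kms_d30, tree.dbh_cm)
    return tree.moe_est


def predict_all(model: LinearMOEModel, trees: Iterable[TreeRecord]) -> list[TreeRecord]:
    trees = list(trees)
    for t in trees:
        predict_moe(model, t)
    return trees


def model_diagnostics(
    model: LinearMOEModel, trees: Sequence[TreeRecord]
) -> FitDiagnostics:
    """R² (squared obs–pred correlation), RMSE, and mean percentage error.

    E% = mean((observed − predicted)/observed) × 100, observed denominator.
    """
    obs = np.array([t.moe_observed for t in trees], dtype=float)
    if np.any(obs == 0):
        raise ValueError("observed MOE of zero: percentage error undefined")
    pred = np.array([model.predict(t.velocity_kms_d30, t.dbh_cm) for t in trees])
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        r2 = 1.0 if np.allclose(obs, pred) else 0.0
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    e_pct = float(np.mean(resid / obs) * 100.0)
    return FitDiagnostics(r_squared=r2, rmse=rmse, e_pct=e_pct)
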