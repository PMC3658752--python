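"""NLGA SPS-2 machine stress-rated grade arithmetic and logistic pass models.

MSR grade names encode two design values: ``<Fb>Fb-<E>E`` where Fb is the
allowable bending stress (psi) and E the mean stiffness (Mpsi).  Metric
requirements follow from 1 psi = 6,894.757 Pa, rounded to one decimal for
the threshold tables (10.3/12.4/13.8 GPa and 11.4/14.5/16.6 MPa for the
three grades assessed here).  A board passes a grade when it passed visual
grading (No. 2 & Better) and its static MOE meets the grade's stiffness
requirement; only stiffness drives grading here, the strength threshold is
carried as metadata.

Per-grade pass proportions are modelled board-level by logistic regression
on the predicted tree stiffness MOE_est:

    P(pass) = logit⁻¹(θ₁ + θ₂·MOE_est)

with the slope dropped (intercept-only) when its Wald test is not
significant.  Boards from the same tree are treated as independent — a
simplification mirrored from the original analysis; see docs/methods.md.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit

from . import presets
from .moe_model import TreeRecord

PSI_TO_PA = 6_894.757  # exact definition; drives the stiffness thresholds
#: Strength design values use the round lumber-standard conversion
#: 145 psi = 1 MPa (it reproduces the published 11.4/14.5/16.6 MPa table,
#: which the exact factor does not: 2400/145.0377 = 16.55 rounds to 16.5).
PSI_PER_MPA = 145.0

_GRADE_RE = re.compile(r"^(?P<fb>\d+(?:\.\d+)?)Fb-(?P<e>\d+(?:\.\d+)?)E$")


@dataclass(frozen=True)
class MSRGrade:
    """A machine stress-rated lumber grade and its metric requirements."""

    name: str
    stiffness_mpsi: float
    strength_psi: float
    stiffness_required_gpa: float  # rounded to 1 decimal; used for grading
    strength_required_mpa: float  # rounded to 1 decimal; metadata only
    stiffness_required_gpa_exact: float
    strength_required_mpa_exact: float


def parse_grade(name: str) -> MSRGrade:
    """Parse ``"<Fb>Fb-<E>E"`` and derive the metric requirement thresholds."""
    m = _GRADE_RE.match(name)
    if m is None:
        raise ValueError(f"malformed MSR grade name: {name!r}")
    fb_psi = float(m.group("fb"))
    e_mpsi = float(m.group("e"))
    e_gpa = e_mpsi * PSI_TO_PA * 1e-3  # Mpsi -> GPa
    fb_mpa = fb_psi / PSI_PER_MPA  # psi -> MPa, 145 psi = 1 MPa convention
    return MSRGrade(
        name=name,
        stiffness_mpsi=e_mpsi,
        strength_psi=fb_psi,
        stiffness_required_gpa=round(e_gpa, 1),
        strength_required_mpa=round(fb_mpa, 1),
        stiffness_required_gpa_exact=e_gpa,
        strength_required_mpa_exact=fb_mpa,
    )


def default_grades() -> tuple[MSRGrade, ...]:
    """The three case-study grades, weakest to strictest."""
    return tuple(parse_grade(n) for n in presets.GRADE_NAMES)


@dataclass
class BoardRecord:
    """One sawn piece with its static bending MOE and grading flags."""

    board_id: str
    tree_id: str
    moe_static: float  # kN·mm⁻² at 15% moisture content
    visual_pass: bool = True  # No. 2 & Better visual grade
    grade_pass: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.moe_static <= 0:
            raise ValueError("static MOE must be positive")


def grade_boards(
    boards: Iterable[BoardRecord], grades: Sequence[MSRGrade]
) -> list[BoardRecord]:
    """Assign per-grade pass flags: visual pass AND MOE ≥ stiffness threshold.

    Ties pass (``≥``).  Flags are monotone across nested thresholds by
    construction.  Empty input yields empty output.
    """
    boards = list(boards)
    for b in boards:
        for g in grades:
            b.grade_pass[g.name] = bool(
                b.visual_pass and b.moe_static >= g.stiffness_required_gpa
            )
    return boards


@dataclass(frozen=True)
class GradePassModel:
    """Logistic pass curve for one grade: logit⁻¹(θ₁ + θ₂·MOE_est).

    ``theta2 is None`` flags an intercept-only model (constant pass
    probability).  ``degenerate`` marks fits that hit complete separation or
    a single-outcome sample; such models carry their fitted constant but are
    flagged unusable for inference.
    """

    grade: str
    theta1: float
    theta2: float | None = None
    slope_p_value: float | None = None
    stderr: tuple[float, ...] | None = None
    degenerate: bool = False
    n_boards: int | None = None

    @property
    def intercept_only(self) -> bool:
        return self.theta2 is None

    @property
    def usable(self) -> bool:
        return not self.degenerate


def preset_grade_models() -> dict[str, GradePassModel]:
    """The published per-grade logistic coefficients, keyed by grade name."""
    out = {}
    for name, (t1, t2) in presets.LOGISTIC_PRESETS.items():
        out[name] = GradePassModel(grade=name, theta1=t1, theta2=t2)
    return out


def pass_probability(model: GradePassModel, moe_est: float) -> float:
    """Inverse-logit evaluation, numerically stable for large |η|."""
    x = np.asarray(moe_est, dtype=float)
    eta = model.theta1 + (model.theta2 if model.theta2 is not None else 0.0) * x
    return expit(eta) if np.ndim(moe_est) else float(expit(eta))


def fit_grade_model(
    boards: Sequence[BoardRecord],
    trees: Sequence[TreeRecord] | Mapping[str, float],
    grade: MSRGrade | str,
    alpha: float = 0.05,
    force_intercept_only: bool = False,
) -> GradePassModel:
    """Board-level Bernoulli regression of grade pass on tree MOE_est.

    ``trees`` supplies MOE_est per tree id (records or a mapping).  If the
    slope's Wald p-value exceeds ``alpha`` the model is refitted
    intercept-only, whose MLE is the closed-form logit of the pass fraction.
    Complete separation or an all-same-outcome sample returns a degenerate
    flagged model rather than raising.
    """
    grade_name = grade.name if isinstance(grade, MSRGrade) else grade
    if isinstance(trees, Mapping):
        moe_by_tree = dict(trees)
    else:
        moe_by_tree = {t.tree_id: t.moe_est for t in trees}
    y, x = [], []
    for b in boards:
        if grade_name not in b.grade_pass:
            raise ValueError(f"board {b.board_id} not graded against {grade_name}")
        moe = moe_by_tree.get(b.tree_id)
        if moe is None:
            raise ValueError(f"tree {b.tree_id} lacks MOE_est")
        y.append(1.0 if b.grade_pass[grade_name] else 0.0)
        x.append(moe)
    y_arr = np.asarray(y)
    x_arr = np.asarray(x)
    n = len(y_arr)
    if n == 0:
        raise ValueError("no boards to fit")

    p_hat = float(y_arr.mean())
    if p_hat in (0.0, 1.0):
        # single-outcome sample: constant model at the boundary
        return GradePassModel(
            grade=grade_name,
            theta1=math.inf if p_hat == 1.0 else -math.inf,
            degenerate=True,
            n_boards=n,
        )
    if force_intercept_only:
        return GradePassModel(
            grade=grade_name, theta1=float(logit(p_hat)), n_boards=n
        )

    X = sm.add_constant(x_arr)
    try:
        import warnings

        with warnings.catch_warnings():
            # separation surfaces as a statsmodels warning plus non-finite
            # estimates; we detect it below and flag the model instead
            warnings.simplefilter("ignore")
            res = sm.Logit(y_arr, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        params_ok = np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))
    except Exception:
        converged = params_ok = False
        res = None
    if res is None or not (converged and params_ok):
        # complete separation (or other failure): report, flag unusable
        return GradePassModel(
            grade=grade_name,
            theta1=float(logit(p_hat)),
            degenerate=True,
            n_boards=n,
        )
    slope_p = float(res.pvalues[1])
    if slope_p > alpha:
        return GradePassModel(
            grade=grade_name,
            theta1=float(logit(p_hat)),
            slope_p_value=slope_p,
            n_boards=n,
        )
    return GradePassModel(
        grade=grade_name,
        theta1=float(res.params[0]),
        theta2=float(res.params[1]),
        slope_p_value=slope_p,
        stderr=tuple(float(s) for s in res.bse),
        n_boards=n,
    )


def fit_all_grade_models(
    boards: Sequence[BoardRecord],
    trees: Sequence[TreeRecord],
    grades: Sequence[MSRGrade] | None = None,
    alpha: float = 0.05,
) -> dict[str, GradePassModel]:
    grades = tuple(grades) if grades is not None else default_grades()
    return {g.name: fit_grade_model(boards, trees, g, alpha=alpha) for g in grades}
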