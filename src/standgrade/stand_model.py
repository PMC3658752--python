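"""Plot expansion, per-stratum MOE distributions, and TSF-class comparisons.

Trees were tallied with a variable-radius (prism) plot of basal area factor
BAF m²·ha⁻¹, so each counted stem represents BAF divided by its own basal
area stems per hectare: weight = BAF · 40,000/(π·DBH²), which at BAF = 2 is
the classical 80,000/(π·DBH²) correction.  Per-hectare weighting lets the
plot sample speak for the stand: the stratum MOE_est distribution is
summarised by the expansion-weighted mean and SD and treated as normal when
integrating pass rates downstream.

Stratum comparisons use one-way ANOVA with Tukey HSD multiple comparisons
and a compact letter display (shared letter ⇔ not significantly different).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .moe_model import TreeRecord
from .presets import BASAL_AREA_FACTOR

SQ_M_PER_SQ_CM = 1.0 / 40_000.0  # π·DBH²/4 in cm² -> m² basal area per stem


@dataclass(frozen=True)
class TSFClass:
    """A time-since-fire stratum, bounds in years (upper may be open)."""

    label: str
    lower: float
    upper: float | None = None

    def contains(self, tsf_years: float) -> bool:
        return tsf_years >= self.lower and (self.upper is None or tsf_years <= self.upper)


DEFAULT_TSF_CLASSES: tuple[TSFClass, ...] = (
    TSFClass("50-99", 50, 99),
    TSFClass("100-149", 100, 149),
    TSFClass("150-199", 150, 199),
    TSFClass(">200", 200, None),
)


@dataclass(frozen=True)
class StandDistribution:
    """Per-hectare-weighted normal summary of MOE_est for one stratum."""

    stratum: str
    mu: float  # kN·mm⁻²
    sigma: float
    moe_min: float
    moe_max: float
    stems_per_ha: float
    n_trees: int
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def expansion_weight(dbh_cm: float, baf: float = BASAL_AREA_FACTOR) -> float:
    """Stems per hectare represented by one prism-counted tree.

    weight = BAF × 40,000/(π·DBH²); at BAF = 2, exactly 80,000/(π·DBH²).
    The identity weight × (π·DBH²/40,000 m²) = BAF holds for any DBH.
    """
    if dbh_cm <= 0:
        raise ValueError("DBH must be positive")
    if baf <= 0:
        raise ValueError("basal area factor must be positive")
    return baf * 40_000.0 / (math.pi * dbh_cm**2)


def basal_area_m2(dbh_cm: float) -> float:
    """Per-tree basal area π·DBH²/40,000 in m² (DBH in cm)."""
    return math.pi * dbh_cm**2 * SQ_M_PER_SQ_CM


def stand_distribution(
    trees: Sequence[TreeRecord],
    stratum: str,
    weighting: bool = True,
    baf: float = BASAL_AREA_FACTOR,
) -> StandDistribution:
    """Frequency-weighted mean and SD of MOE_est for one stratum.

    With ``weighting`` on, each tree counts its expansion weight (stems/ha);
    off, unit weights.  The weighted SD uses the frequency-weight form
    √(Σwᵢ(xᵢ−μ)²/Σwᵢ), appropriate because expansion factors are stem
    counts, not precision weights.
    """
    members = [t for t in trees if t.tsf_class == stratum]
    if len(members) < 2:
        raise ValueError(f"need at least 2 trees in stratum {stratum!r}")
    x = np.array([t.moe_est for t in members], dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("all trees must carry MOE_est")
    w = (
        np.array([expansion_weight(t.dbh_cm, baf) for t in members])
        if weighting
        else np.ones(len(members))
    )
    w_tot = float(w.sum())
    if w_tot <= 0:
        raise ValueError("zero total expansion weight")
    mu = float(np.sum(w * x) / w_tot)
    sigma = float(np.sqrt(np.sum(w * (x - mu) ** 2) / w_tot))
    stems = float(
        np.sum([expansion_weight(t.dbh_cm, baf) for t in members])
    )
    return StandDistribution(
        stratum=stratum,
        mu=mu,
        sigma=sigma,
        moe_min=float(x.min()),
        moe_max=float(x.max()),
        stems_per_ha=stems,
        n_trees=len(members),
        weighted=weighting,
    )


def all_stand_distributions(
    trees: Sequence[TreeRecord],
    weighting: bool = True,
    baf: float = BASAL_AREA_FACTOR,
) -> dict[str, StandDistribution]:
    strata = sorted({t.tsf_class for t in trees})
    return {s: stand_distribution(trees, s, weighting, baf) for s in strata}


def normal_density(x, mu: float, sigma: float):
    """Gaussian pdf P(x) = exp(−(x−μ)²/2σ²)/(σ√2π); σ must be positive."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return stats.norm.pdf(x, loc=mu, scale=sigma)


def normality_report(trees: Sequence[TreeRecord]) -> pd.DataFrame:
    """Skewness/excess-kurtosis diagnostic of MOE_est per stratum.

    Purely informational — the downstream integration assumes normality and
    this report never gates computation.
    """
    rows = []
    for stratum in sorted({t.tsf_class for t in trees}):
        x = np.array([t.moe_est for t in trees if t.tsf_class == stratum], float)
        rows.append(
            {
                "stratum": stratum,
                "n": len(x),
                "skewness": float(stats.skew(x)) if len(x) > 2 else math.nan,
                "excess_kurtosis": float(stats.kurtosis(x)) if len(x) > 3 else math.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassComparison:
    """One-way ANOVA with Tukey HSD pairwise letters for a tree attribute."""

    variable: str
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p-adj, reject
    letters: dict[str, str]  # compact letter display per stratum
    means: dict[str, float]


_VARIABLES = {
    "velocity": lambda t: t.velocity_kms_d30,
    "moe_est": lambda t: t.moe_est,
    "dbh": lambda t: t.dbh_cm,
}


def compare_classes(
    trees: Sequence[TreeRecord], variable: str = "moe_est", alpha: float = 0.05
) -> ClassComparison:
    """ANOVA F-test across TSF classes plus Tukey HSD letter codes."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if variable not in _VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; one of {sorted(_VARIABLES)}")
    getter = _VARIABLES[variable]
    by_class: dict[str, list[float]] = {}
    for t in trees:
        by_class.setdefault(t.tsf_class, []).append(float(getter(t)))
    if len(by_class) < 2:
        raise ValueError("need at least two strata")
    for label, vals in by_class.items():
        if len(vals) < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 trees")
    groups = sorted(by_class)
    f_stat, p_val = stats.f_oneway(*(by_class[g] for g in groups))

    values = np.concatenate([by_class[g] for g in groups])
    labels = np.concatenate([[g] * len(by_class[g]) for g in groups])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    nonsig = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey_df.iterrows()
        if not row["reject"]
    }
    means = {g: float(np.mean(by_class[g])) for g in groups}
    letters = _compact_letters(groups, nonsig, means)
    return ClassComparison(
        variable=variable,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        tukey=tukey_df,
        letters=letters,
        means=means,
    )


def _compact_letters(
    groups: Sequence[str],
    nonsig_pairs: set[frozenset],
    means: Mapping[str, float],
) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Maximal cliques of the "not significantly different" graph each receive
    one letter, ordered by descending clique-best mean, so two strata share
    a letter exactly when no test separates them.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(tuple(p) for p in nonsig_pairs if len(p) == 2)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters: dict[str, str] = {grp: "" for grp in groups}
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            letters[member] += letter
    return {grp: "".join(sorted(s)) for grp, s in letters.items()}


def stand_summary_table(
    trees: Sequence[TreeRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-class survey-style summary: n, velocity/MOE_est/DBH mean and SD,
    with Tukey letters for velocity and MOE_est.  Both arithmetic and
    expansion-weighted MOE_est means are reported, labelled."""
    vel_cmp = compare_classes(trees, "velocity", alpha)
    moe_cmp = compare_classes(trees, "moe_est", alpha)
    rows = []
    for stratum in sorted({t.tsf_class for t in trees}):
        members = [t for t in trees if t.tsf_class == stratum]
        vel = np.array([t.velocity_kms_d30 for t in members])
        moe = np.array([t.moe_est for t in members], float)
        dbh = np.array([t.dbh_cm for t in members])
        wdist = stand_distribution(trees, stratum, weighting=True)
        rows.append(
            {
                "tsf_class": stratum,
                "n": len(members),
                "velocity_mean": vel.mean(),
                "velocity_sd": vel.std(ddof=1),
                "velocity_letters": vel_cmp.letters[stratum],
                "moe_est_mean": moe.mean(),
                "moe_est_sd": moe.std(ddof=1),
                "moe_est_letters": moe_cmp.letters[stratum],
                "moe_est_mean_weighted": wdist.mu,
                "moe_est_sd_weighted": wdist.sigma,
                "dbh_mean": dbh.mean(),
                "dbh_sd": dbh.std(ddof=1),
                "stems_per_ha": wdist.stems_per_ha,
            }
        )
    return pd.DataFrame(rows)
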