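"""Expansion weights, weighted stand distributions, class comparisons."""

import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from standgrade.moe_model import TreeRecord
from standgrade.presets import SURVEY_CLASSES
from standgrade.stand_model import (
    basal_area_m2,
    compare_classes,
    expansion_weight,
    normal_density,
    normality_report,
    stand_distribution,
    stand_summary_table,
)


def _tree(i, dbh, moe, stratum="s", v=4.5):
    return TreeRecord(f"t{i}", f"p{i}", stratum, dbh, v, moe_est=moe)


class TestExpansionWeight:
    def test_prism_factor_two_value(self):
        # 80,000/(pi*400) stems/ha for a 20 cm stem under a factor-2 prism
        assert expansion_weight(20.0, baf=2.0) == pytest.approx(63.6619772, abs=1e-6)

    @given(dbh=st.floats(0.5, 150.0), baf=st.floats(0.5, 10.0))
    def test_weight_times_basal_area_is_baf(self, dbh, baf):
        assert expansion_weight(dbh, baf) * basal_area_m2(dbh) == pytest.approx(
            baf, rel=1e-12
        )

    def test_doubling_dbh_quarters_weight(self):
        assert expansion_weight(40.0) == pytest.approx(expansion_weight(20.0) / 4)

    def test_nonpositive_dbh_rejected(self):
        with pytest.raises(ValueError):
            expansion_weight(0.0)


class TestStandDistribution:
    def test_constant_weights_reduce_to_unweighted(self):
        trees = [_tree(i, 18.0, 9.0 + i) for i in range(6)]
        w = stand_distribution(trees, "s", weighting=True)
        u = stand_distribution(trees, "s", weighting=False)
        assert w.mu == pytest.approx(u.mu, rel=1e-12)
        assert w.sigma == pytest.approx(u.sigma, rel=1e-12)

    def test_hand_weighted_mean(self):
        # weights proportional to 1/DBH^2: DBH ratio sqrt(3) gives 3:1
        trees = [_tree(0, 10.0, 10.0), _tree(1, 10.0 * math.sqrt(3), 12.0)]
        d = stand_distribution(trees, "s", weighting=True)
        assert d.mu == pytest.approx(10.5, rel=1e-9)

    def test_recovers_configured_moments_unweighted(self):
        rng = np.random.default_rng(8)
        n, mean, sd = 10_000, 11.16, 1.61
        trees = [_tree(i, 18.0, rng.normal(mean, sd)) for i in range(n)]
        d = stand_distribution(trees, "s", weighting=False)
        assert abs(d.mu - mean) < 3 * sd / math.sqrt(n)
        assert d.sigma == pytest.approx(sd, rel=0.05)
        assert d.moe_min <= d.mu <= d.moe_max
        assert d.n_trees == n

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        trees = [_tree(i, 10 + 10 * rng.random(), 9 + 3 * rng.random())
                 for i in range(50)]
        shuffled = trees[:]
        random.Random(1).shuffle(shuffled)
        a = stand_distribution(trees, "s")
        b = stand_distribution(shuffled, "s")
        assert (a.mu, a.sigma, a.stems_per_ha) == pytest.approx(
            (b.mu, b.sigma, b.stems_per_ha)
        )

    def test_single_tree_stratum_rejected(self):
        with pytest.raises(ValueError):
            stand_distribution([_tree(0, 18.0, 11.0)], "s")


class TestNormalDensity:
    def test_mode_value(self):
        assert normal_density(0.0, 0.0, 1.0) == pytest.approx(0.39894, abs=1e-5)

    @given(a=st.floats(0.0, 5.0))
    def test_even_symmetry(self, a):
        assert normal_density(10 + a, 10.0, 1.3) == pytest.approx(
            normal_density(10 - a, 10.0, 1.3), rel=1e-12
        )

    def test_integrates_to_one(self):
        val, _ = integrate.quad(lambda x: normal_density(x, 11.0, 1.45), 11 - 8 * 1.45,
                                11 + 8 * 1.45)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            normal_density(0.0, 0.0, 0.0)


class TestCompareClasses:
    def test_identically_distributed_classes_share_a_letter(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(11, 1.5, 60)
        trees = [_tree(i, 18.0, v, stratum="a") for i, v in enumerate(vals[:30])]
        trees += [_tree(30 + i, 18.0, v, stratum="b") for i, v in enumerate(vals[30:])]
        cmpres = compare_classes(trees, "moe_est")
        assert set(cmpres.letters["a"]) & set(cmpres.letters["b"])

    def test_extreme_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(3)
        trees = [_tree(i, 18.0, rng.normal(10, 1), stratum="lo") for i in range(50)]
        trees += [_tree(50 + i, 18.0, rng.normal(20, 1), stratum="hi")
                  for i in range(50)]
        cmpres = compare_classes(trees, "moe_est")
        assert not (set(cmpres.letters["lo"]) & set(cmpres.letters["hi"]))
        assert cmpres.p_value < 1e-10

    def test_oldest_class_usually_separates_from_young_classes(self):
        """At the survey's per-class MOE_est moments and sample sizes, the
        >200-year stratum separates from both younger strata in a majority
        of replicates (the direction the survey reports; the exact printed
        letters are not asserted)."""
        cases = {c.label: c for c in SURVEY_CLASSES}
        picks = [cases["50-99"], cases["100-149"], cases[">200"]]
        separated = 0
        n_rep = 25
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            trees = []
            for c in picks:
                for i in range(c.n):
                    trees.append(
                        _tree(f"{c.label}-{i}", 18.0,
                              rng.normal(c.moe_est_mean, c.moe_est_sd),
                              stratum=c.label)
                    )
            cmpres = compare_classes(trees, "moe_est")
            old = set(cmpres.letters[">200"])
            if not (old & set(cmpres.letters["50-99"])) and not (
                old & set(cmpres.letters["100-149"])
            ):
                separated += 1
        assert separated > n_rep / 2

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            compare_classes([_tree(0, 18.0, 11.0)], "height")

    def test_single_stratum_rejected(self):
        trees = [_tree(i, 18.0, 11.0 + i) for i in range(5)]
        with pytest.raises(ValueError):
            compare_classes(trees, "moe_est")


def test_stand_summary_and_normality_report():
    rng = np.random.default_rng(6)
    trees = []
    for c in SURVEY_CLASSES[:2]:
        for i in range(c.n):
            trees.append(
                TreeRecord(
                    f"{c.label}-{i}", f"p{i % 15}", c.label,
                    max(rng.normal(c.dbh_mean, c.dbh_sd), 9.0),
                    rng.normal(c.velocity_mean, c.velocity_sd),
                    moe_est=float(rng.normal(c.moe_est_mean, c.moe_est_sd)),
                )
            )
    table = stand_summary_table(trees)
    assert list(table["tsf_class"]) == ["100-149", "50-99"]
    assert set(table.columns) >= {
        "n", "velocity_mean", "velocity_sd", "velocity_letters",
        "moe_est_mean", "moe_est_sd", "moe_est_letters",
        "moe_est_mean_weighted", "dbh_mean", "stems_per_ha",
    }
    assert (table["n"] == [79, 75]).all()
    rep = normality_report(trees)
    assert set(rep["stratum"]) == {"50-99", "100-149"}
    assert rep["skewness"].abs().max() < 1.0  # generated normal: mild skew only
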