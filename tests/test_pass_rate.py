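"""Logistic-normal pass-rate integration against its Monte Carlo oracle."""

import numpy as np
import pytest
from scipy.special import expit

from standgrade.msr_grades import GradePassModel, pass_probability, preset_grade_models
from standgrade.pass_rate import (
    pass_rate_montecarlo,
    pass_rate_quadrature,
    pass_rate_table,
    regional_pass_rate,
    verification_report,
)
from standgrade.presets import SURVEY_CLASSES
from standgrade.stand_model import StandDistribution


def _dist(mu, sigma, stratum="s", stems=100.0):
    return StandDistribution(stratum, mu, sigma, mu - 4 * sigma, mu + 4 * sigma,
                             stems, 50)


def _survey_dists():
    return {
        c.label: _dist(c.moe_est_mean, c.moe_est_sd, c.label, stems=float(c.n))
        for c in SURVEY_CLASSES
    }


class TestQuadrature:
    def test_degenerate_sigma_limit_equals_pass_curve(self):
        for m in preset_grade_models().values():
            r = pass_rate_quadrature(_dist(11.12, 1e-6), m)
            assert r.pass_rate == pytest.approx(
                pass_probability(m, 11.12), abs=1e-6
            )

    def test_intercept_only_integrand_is_constant(self):
        m = preset_grade_models()["1650Fb-1.5E"]
        r = pass_rate_quadrature(_dist(9.0, 2.0), m)
        assert r.pass_rate == pytest.approx(expit(2.2442), abs=1e-9)

    def test_agrees_with_monte_carlo_oracle(self):
        m = preset_grade_models()["2100Fb-1.8E"]
        d = _dist(11.12, 1.45)
        q = pass_rate_quadrature(d, m)
        mc = pass_rate_montecarlo(d, m, n_draws=1_000_000, seed=0)
        assert abs(q.pass_rate - mc.pass_rate) < 3 * mc.numerical_error

    def test_monotone_increasing_in_mu(self):
        m = preset_grade_models()["2400Fb-2.0E"]
        rates = [pass_rate_quadrature(_dist(mu, 1.2), m).pass_rate
                 for mu in (9.0, 10.5, 12.0, 13.5)]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_result_within_pass_curve_range_over_bounds(self):
        m = preset_grade_models()["2400Fb-2.0E"]
        d = _dist(11.0, 1.3)
        r = pass_rate_quadrature(d, m, bounds=(9.0, 13.0), renormalize=True)
        lo = pass_probability(m, 9.0)
        hi = pass_probability(m, 13.0)
        assert lo <= r.pass_rate <= hi

    def test_literal_truncated_mode_below_renormalized(self):
        m = preset_grade_models()["2100Fb-1.8E"]
        d = _dist(11.12, 1.45)
        literal = pass_rate_quadrature(d, m, bounds=(d.moe_min, d.moe_max),
                                       renormalize=False)
        conditional = pass_rate_quadrature(d, m, bounds=(d.moe_min, d.moe_max),
                                           renormalize=True)
        assert literal.pass_rate < conditional.pass_rate
        assert not literal.renormalized

    def test_empty_interval_rejected(self):
        m = preset_grade_models()["2100Fb-1.8E"]
        with pytest.raises(ValueError):
            pass_rate_quadrature(_dist(11.0, 1.0), m, bounds=(12.0, 12.0))

    def test_unusable_model_rejected(self):
        bad = GradePassModel("g", theta1=2.0, degenerate=True)
        with pytest.raises(ValueError):
            pass_rate_quadrature(_dist(11.0, 1.0), bad)


class TestMonteCarlo:
    def test_intercept_only_exact(self):
        m = preset_grade_models()["1650Fb-1.5E"]
        r = pass_rate_montecarlo(_dist(10.0, 1.5), m, n_draws=2_000, seed=1)
        assert r.pass_rate == pytest.approx(expit(2.2442), abs=1e-12)
        assert r.numerical_error == pytest.approx(0.0, abs=1e-15)

    def test_seeded_reproducibility(self):
        m = preset_grade_models()["2100Fb-1.8E"]
        a = pass_rate_montecarlo(_dist(11.0, 1.5), m, n_draws=10_000, seed=5)
        b = pass_rate_montecarlo(_dist(11.0, 1.5), m, n_draws=10_000, seed=5)
        assert a.pass_rate == b.pass_rate

    def test_stochastically_monotone_in_mu(self):
        m = preset_grade_models()["2400Fb-2.0E"]
        lo = pass_rate_montecarlo(_dist(10.0, 1.2), m, n_draws=50_000, seed=2)
        hi = pass_rate_montecarlo(_dist(12.0, 1.2), m, n_draws=50_000, seed=2)
        assert hi.pass_rate > lo.pass_rate

    def test_too_few_draws_rejected(self):
        m = preset_grade_models()["2100Fb-1.8E"]
        with pytest.raises(ValueError):
            pass_rate_montecarlo(_dist(11.0, 1.0), m, n_draws=10)

    def test_cross_method_consistency_grid(self):
        """Quadrature and the Monte Carlo oracle agree within 3 MC standard
        errors over a (mu, sigma, grade) grid."""
        models = preset_grade_models()
        k = 0
        for mu in (9.0, 10.5, 12.0):
            for sigma in (0.5, 1.5):
                for m in models.values():
                    d = _dist(mu, sigma)
                    q = pass_rate_quadrature(d, m)
                    mc = pass_rate_montecarlo(d, m, n_draws=100_000, seed=40 + k)
                    assert abs(q.pass_rate - mc.pass_rate) <= (
                        3 * mc.numerical_error + 1e-9
                    )
                    k += 1


class TestTableAndRegional:
    def test_single_intercept_only_cell(self):
        models = {"1650Fb-1.5E": preset_grade_models()["1650Fb-1.5E"]}
        table = pass_rate_table({"s": _dist(11.0, 1.2)}, models)
        assert table.shape == (1, 1)
        assert table.iloc[0, 0] == pytest.approx(round(100 * expit(2.2442), 1))

    def test_survey_matrix_monotone_across_grades(self):
        table = pass_rate_table(_survey_dists(), preset_grade_models())
        assert table.shape == (4, 3)
        for _, row in table.iterrows():
            assert row["1650Fb-1.5E"] >= row["2100Fb-1.8E"] >= row["2400Fb-2.0E"]
        # intercept-only grade constant across strata
        assert row_constant(table["1650Fb-1.5E"])

    def test_identical_strata_pool_to_component_rate(self):
        m = preset_grade_models()["2100Fb-1.8E"]
        dists = {"a": _dist(11.0, 1.3, "a"), "b": _dist(11.0, 1.3, "b")}
        pooled = regional_pass_rate(dists, m, {"all": ["a", "b"]})["all"]
        single = pass_rate_quadrature(dists["a"], m)
        assert pooled.pass_rate == pytest.approx(single.pass_rate, abs=1e-9)

    def test_mixture_is_convex_combination(self):
        m = preset_grade_models()["2400Fb-2.0E"]
        dists = {"a": _dist(10.5, 1.2, "a", stems=30.0),
                 "b": _dist(12.0, 0.8, "b", stems=70.0)}
        pooled = regional_pass_rate(dists, m, {"all": ["a", "b"]})["all"]
        pa = pass_rate_quadrature(dists["a"], m).pass_rate
        pb = pass_rate_quadrature(dists["b"], m).pass_rate
        expected = (30 * pa + 70 * pb) / 100
        assert pooled.pass_rate == pytest.approx(expected, abs=1e-9)
        assert min(pa, pb) <= pooled.pass_rate <= max(pa, pb)

    def test_young_group_exceeds_old_group_for_top_grade(self):
        """Pooling the survey strata into 50–149 vs >150 years, the younger
        group clears the strictest grade at a strictly higher rate."""
        m = preset_grade_models()["2400Fb-2.0E"]
        out = regional_pass_rate(
            _survey_dists(), m,
            {"50-149": ["50-99", "100-149"], ">150": ["150-199", ">200"]},
        )
        assert out["50-149"].pass_rate > out[">150"].pass_rate

    def test_grouping_must_partition(self):
        m = preset_grade_models()["2100Fb-1.8E"]
        with pytest.raises(ValueError):
            regional_pass_rate(_survey_dists(), m, {"partial": ["50-99"]})

    def test_verification_report_all_within_three_se(self):
        rep = verification_report(_survey_dists(), preset_grade_models(),
                                  n_draws=50_000, seed=3)
        assert len(rep) == 12
        assert bool(rep["within_3_se"].all())


def row_constant(col) -> bool:
    return float(col.max() - col.min()) == 0.0
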