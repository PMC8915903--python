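"""Lognormal fitting, 5th-percentile estimation, and threshold derivation."""

import math

import numpy as np
import pytest

from ttckit.records import AdjustedPOD, CramerClass, StudyRecord
from ttckit.ttc_stats import (
    class_summary,
    derive_threshold,
    fit_lognormal,
    lognormal_p5,
    render_threshold,
    round_sig,
    run_ttc_analysis,
)


def make_adjusted(pods, cls="III"):
    return [
        AdjustedPOD(
            substance_id=f"{cls}-{i}",
            raw_effect_level=p * 6,
            loael_factor_applied=1,
            duration_factor_applied=6,
            adjusted_pod=p,
            study=StudyRecord(
                substance_id=f"{cls}-{i}",
                source="synthetic",
                route="gavage",
                duration_days=30,
                effect_level_type="NOAEL",
                effect_level=p * 6,
                reliability_rank=1,
            ),
        )
        for i, p in enumerate(pods)
    ]


class TestFitLognormal:
    def test_constant_sample(self):
        assert fit_lognormal([1.0, 1.0, 1.0]) == (0.0, 0.0)

    def test_two_point_sample(self):
        mu, sigma = fit_lognormal([math.exp(0), math.exp(2)])
        assert mu == pytest.approx(1.0)
        assert sigma == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(42)
        draws = np.exp(rng.normal(1.0, 0.5, size=10_000))
        mu, sigma = fit_lognormal(draws)
        assert mu == pytest.approx(1.0, rel=0.02)
        assert sigma == pytest.approx(0.5, rel=0.02)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_lognormal([1.0])
        with pytest.raises(ValueError):
            fit_lognormal([1.0, -2.0])


class TestLognormalP5:
    def test_degenerate(self):
        assert lognormal_p5(0.0, 0.0) == 1.0

    def test_published_class_parameters(self):
        # closed-form evaluation at the published class III / class I fits
        assert lognormal_p5(math.log(4.7), 1.951) == pytest.approx(0.19, abs=0.005)
        assert lognormal_p5(math.log(12.5), 1.606) == pytest.approx(0.89, abs=0.005)

    def test_monotonicity(self):
        assert lognormal_p5(0.0, 2.0) < lognormal_p5(0.0, 1.0)
        assert lognormal_p5(1.0, 1.0) > lognormal_p5(0.0, 1.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            lognormal_p5(0.0, -0.1)

    def test_parametric_matches_empirical_at_large_n(self):
        rng = np.random.default_rng(7)
        draws = np.exp(rng.normal(math.log(4.7), 1.951, size=10_000))
        mu, sigma = fit_lognormal(draws)
        parametric = lognormal_p5(mu, sigma)
        empirical = float(np.quantile(draws, 0.05))
        assert parametric == pytest.approx(empirical, rel=0.03)


class TestDeriveThreshold:
    def test_chaining_identity(self):
        t = derive_threshold(0.37, n=100, uf=100, body_weight_kg=60)
        recovered = t.threshold_ug_person_day / 60.0 / 1000.0 * 100.0
        assert math.isclose(recovered, 0.37, rel_tol=1e-12)

    def test_reliability_guard(self):
        t = derive_threshold(1.0, n=10, min_n=30)
        assert t.tdi_ug_kg_day == pytest.approx(10.0)
        assert t.threshold_ug_person_day == pytest.approx(600.0)
        assert t.reliable is False
        assert derive_threshold(1.0, n=30, min_n=30).reliable is True

    def test_nonpositive_inputs_rejected(self):
        for bad in [dict(pod_p5=0.0), dict(uf=0.0), dict(body_weight_kg=-1.0)]:
            with pytest.raises(ValueError):
                derive_threshold(**{"pod_p5": 1.0, "n": 5, **bad})


class TestClassSummary:
    def test_two_point_example(self):
        s = class_summary([2.0, 8.0])
        assert s.median == pytest.approx(5.0)
        assert s.geometric_mean == pytest.approx(4.0)

    def test_single_point(self):
        s = class_summary([7.0])
        assert s.median == pytest.approx(7.0)
        assert s.geometric_mean == pytest.approx(7.0)

    def test_ecdf_nondecreasing_from_1_over_n_to_1(self):
        s = class_summary([3.0, 1.0, 2.0, 5.0])
        fractions = [f for _, f in s.ecdf]
        logs = [x for x, _ in s.ecdf]
        assert fractions == sorted(fractions)
        assert fractions[0] == pytest.approx(1 / 4)
        assert fractions[-1] == pytest.approx(1.0)
        assert logs == sorted(logs)

    def test_geometric_mean_equals_fitted_median(self):
        """exp(log_mu) and the sample geometric mean are the same estimator."""
        rng = np.random.default_rng(3)
        pods = np.exp(rng.normal(2.0, 1.0, size=101))
        mu, _ = fit_lognormal(pods)
        assert class_summary(list(pods)).geometric_mean == pytest.approx(
            math.exp(mu), rel=1e-12
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            class_summary([])


class TestRunTtcAnalysis:
    def test_small_class_rendered_na(self):
        rng = np.random.default_rng(11)
        groups = {
            CramerClass.I: make_adjusted(np.exp(rng.normal(2.5, 1.6, 190)), "I"),
            CramerClass.II: make_adjusted(np.exp(rng.normal(1.0, 1.0, 22)), "II"),
            CramerClass.III: make_adjusted(np.exp(rng.normal(1.5, 2.0, 444)), "III"),
        }
        report = run_ttc_analysis(groups, min_n=30)
        rendered = {
            t.cramer_class: render_threshold(t) for t in report.thresholds
        }
        assert rendered[CramerClass.II]["tdi_ug_kg_day"] == "NA"
        assert rendered[CramerClass.I]["tdi_ug_kg_day"] != "NA"
        assert rendered[CramerClass.III]["threshold_ug_person_day"] != "NA"
        # accounting: per-class n values sum to the retained dataset size
        assert sum(t.n for t in report.thresholds) == 656

    def test_all_classes_empty(self):
        report = run_ttc_analysis({})
        assert len(report.thresholds) == 3
        assert all(not t.reliable for t in report.thresholds)

    def test_exact_min_n_is_reliable(self):
        rng = np.random.default_rng(5)
        groups = {CramerClass.I: make_adjusted(np.exp(rng.normal(0, 1, 30)), "I")}
        report = run_ttc_analysis(groups, min_n=30)
        assert report.thresholds[0].reliable is True

    def test_uf_scaling_is_linear(self):
        rng = np.random.default_rng(9)
        pods = np.exp(rng.normal(1.0, 1.0, 50))
        base = run_ttc_analysis({CramerClass.I: make_adjusted(pods, "I")}, uf=100)
        tenfold = run_ttc_analysis({CramerClass.I: make_adjusted(pods, "I")}, uf=1000)
        assert tenfold.thresholds[0].tdi_ug_kg_day == pytest.approx(
            base.thresholds[0].tdi_ug_kg_day / 10
        )


def test_round_sig():
    assert round_sig(534.48, 3) == 534.0
    assert round_sig(8.9123, 2) == 8.9
    assert round_sig(0.0, 2) == 0.0
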