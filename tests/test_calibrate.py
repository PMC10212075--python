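"""Gradient fits, growth-curve fits, curation and the egg-count model."""

import numpy as np
import pandas as pd
import pytest

from fishlhopt import (
    AllocationSchedule,
    FecundityModel,
    GrowthParams,
    aggregate_mortality,
    curate_fecundity_table,
    estimate_h,
    fit_a50,
    fit_growth_curve,
    fit_loglinear,
    literature_a50,
    literature_fecundity_coefs,
    literature_gradients,
    predict_at_latitude,
    predict_fecundity,
)
from fishlhopt.growth import weight_at


class TestLogLinearGradient:
    def test_noiseless_exact_recovery(self):
        lat = np.linspace(0, 75, 40)
        values = np.exp(-0.31 - 0.02 * lat)
        res = fit_loglinear(values, lat)
        assert res.a == pytest.approx(-0.31, abs=1e-10)
        assert res.b_lat == pytest.approx(-0.02, abs=1e-12)
        assert res.rsquared == pytest.approx(1.0)

    def test_latitude_sign_equivariance(self, rng):
        lat = rng.uniform(5, 70, 30)
        values = np.exp(1.0 - 0.015 * lat + rng.normal(0, 0.2, 30))
        res_pos = fit_loglinear(values, lat)
        res_neg = fit_loglinear(values, -lat)  # southern-hemisphere encoding
        assert res_pos.a == pytest.approx(res_neg.a)
        assert res_pos.b_lat == pytest.approx(res_neg.b_lat)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            fit_loglinear([0.5, 0.4], [0.0, 10.0])

    def test_nonpositive_values_reported_with_rows(self):
        with pytest.raises(ValueError, match="rows"):
            fit_loglinear([0.5, -0.1, 0.4, 0.3], [0, 10, 20, 30])

    def test_interval_coverage_under_lognormal_noise(self):
        # 95% normal-approximation intervals cover the true intercept in
        # >= 90% of replicates at n = 80, sigma = 0.5
        a_true, b_true, hits = -0.31, -0.02, 0
        reps = 100
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            lat = rng.uniform(0, 75, 80)
            v = np.exp(a_true + b_true * lat + rng.normal(0, 0.5, 80))
            res = fit_loglinear(v, lat)
            lo, hi = res.conf_int()[0]
            hits += lo <= a_true <= hi
        assert hits >= 0.9 * reps


class TestGradientSet:
    def test_coefficient_calibration_endpoints(self, coefficient_gradients):
        M, k, w0 = predict_at_latitude(coefficient_gradients, 0.0)
        assert k == pytest.approx(np.exp(1.47), rel=1e-12)   # ~4.35
        assert w0 == pytest.approx(np.exp(2.67), rel=1e-12)  # ~14.4
        assert M == pytest.approx(np.exp(-0.31), rel=1e-12)

    def test_prediction_calibration_reproduces_point_estimates(self, gradients):
        # the reconstructed gradients hit the published per-latitude values
        _, k20, w20 = gradients.predict(20.0)
        _, k40, w40 = gradients.predict(40.0)
        assert k20 == pytest.approx(3.41, rel=0.005)
        assert w20 == pytest.approx(13.87, rel=0.005)
        assert k40 == pytest.approx(2.68, rel=0.005)
        assert w40 == pytest.approx(13.35, rel=0.005)

    def test_zero_slopes_latitude_independent(self):
        from fishlhopt.calibrate import GradientSet, LogLinearCoefs

        g = GradientSet(*(LogLinearCoefs(0.5, 0.0) for _ in range(3)))
        assert g.predict(0.0) == g.predict(50.0)

    def test_extrapolation_warns(self, gradients):
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_at_latitude(gradients, 80.0)


class TestGrowthCurve:
    def test_noiseless_self_consistency(self):
        gp = GrowthParams(k=4.35, w0=14.4)
        ages = np.linspace(0.2, 5.0, 12)
        s = AllocationSchedule(alpha=10.0, h=0.26)  # all pre-maturity
        res = fit_growth_curve(ages, weight_at(ages, gp, s))
        assert res.k == pytest.approx(gp.k, rel=1e-6)
        assert res.w0 == pytest.approx(gp.w0, rel=1e-6)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_curve([1.0, 2.0], [10.0, 20.0])

    def test_median_recovery_under_multiplicative_noise(self):
        gp = GrowthParams(k=4.35, w0=14.4)
        ages = np.linspace(0.2, 6.0, 12)
        s = AllocationSchedule(alpha=10.0, h=0.26)
        truth_w = weight_at(ages, gp, s)
        rel_err_k = []
        for i in range(50):
            rng = np.random.default_rng(200 + i)
            masses = truth_w * np.exp(rng.normal(0, 0.1, len(ages)))
            res = fit_growth_curve(ages, masses)
            rel_err_k.append(abs(res.k - gp.k) / gp.k)
        assert np.median(rel_err_k) < 0.15

    def test_general_b_pathway(self):
        gp = GrowthParams(k=3.0, w0=8.0, b=2.0 / 3.0)
        ages = np.linspace(0.1, 4.0, 10)
        s = AllocationSchedule(alpha=10.0, h=0.26)
        res = fit_growth_curve(ages, weight_at(ages, gp, s), b=2.0 / 3.0)
        assert res.k == pytest.approx(3.0, rel=1e-6)
        assert res.w0 == pytest.approx(8.0, rel=1e-6)


class TestEstimateH:
    def test_noiseless_recovery(self):
        gp = GrowthParams(k=4.0, w0=14.0)
        s = AllocationSchedule(alpha=3.0, h=0.26)
        ages = np.linspace(0.3, 20.0, 30)
        res = estimate_h(ages, weight_at(ages, gp, s), alpha=3.0)
        assert res.h == pytest.approx(0.26, rel=0.05)
        assert res.k == pytest.approx(4.0, rel=0.01)

    def test_all_premature_ages_rejected(self):
        gp = GrowthParams(k=4.0, w0=14.0)
        s = AllocationSchedule(alpha=10.0, h=0.26)
        ages = np.linspace(0.3, 5.0, 8)
        with pytest.raises(ValueError, match="pre-maturity"):
            estimate_h(ages, weight_at(ages, gp, s), alpha=10.0)

    def test_seeded_recovery_with_noise(self):
        gp = GrowthParams(k=4.0, w0=14.0)
        s = AllocationSchedule(alpha=3.0, h=0.39)
        ages = np.linspace(0.3, 22.0, 40)
        rng = np.random.default_rng(42)
        masses = weight_at(ages, gp, s) * np.exp(rng.normal(0, 0.05, len(ages)))
        res = estimate_h(ages, masses, alpha=3.0)
        assert 0.3 <= res.h <= 0.5

    def test_h_only_fit_with_fixed_growth(self):
        gp = GrowthParams(k=4.0, w0=14.0)
        s = AllocationSchedule(alpha=3.0, h=0.26)
        ages = np.linspace(0.5, 18.0, 20)
        res = estimate_h(ages, weight_at(ages, gp, s), alpha=3.0, gp_init=gp, joint=False)
        assert res.h == pytest.approx(0.26, rel=1e-4)


def _toy_fecundity(rows):
    defaults = {
        "location": "L1",
        "year": 2000,
        "abs_lat": 10.0,
        "mass_g": 100.0,
        "fecundity": 1e4,
        "is_freshwater_migrant": False,
        "is_elasmobranch": False,
        "is_tuna": False,
    }
    return pd.DataFrame([{**defaults, **row} for row in rows])


class TestCuration:
    def test_minimum_points_rule(self):
        rows = [{"species": "A"}] * 12 + [{"species": "B"}] * 8
        curated, report = curate_fecundity_table(_toy_fecundity(rows))
        assert set(curated["species"]) == {"A"}
        assert report.removed["fewer-than-10-points"] == 8
        assert report.retained_rows == 12

    def test_taxon_filter_overrides_counts(self):
        rows = [{"species": "A"}] * 12 + [{"species": "ray", "is_elasmobranch": True}] * 15
        curated, report = curate_fecundity_table(_toy_fecundity(rows))
        assert "ray" not in set(curated["species"])
        assert report.removed["elasmobranch-or-tuna"] == 15

    def test_modal_year_then_count_rule(self):
        # 7 points in 2001, 9 in 2002: the modal year (2002) is kept first,
        # then the species falls below the 10-point threshold and is dropped
        rows = [{"species": "A", "year": 2001}] * 7 + [{"species": "A", "year": 2002}] * 9
        curated, report = curate_fecundity_table(_toy_fecundity(rows))
        assert len(curated) == 0
        assert report.removed["non-modal-year"] == 7
        assert report.removed["fewer-than-10-points"] == 9

    def test_modal_year_tie_keeps_earlier(self):
        rows = [{"species": "A", "year": 2005}] * 10 + [{"species": "A", "year": 2001}] * 10
        curated, _ = curate_fecundity_table(_toy_fecundity(rows))
        assert set(curated["year"]) == {2001}

    def test_idempotence_and_count_conservation(self):
        rows = (
            [{"species": "A"}] * 12
            + [{"species": "B"}] * 8
            + [{"species": "tuna", "is_tuna": True}] * 11
        )
        df = _toy_fecundity(rows)
        once, report = curate_fecundity_table(df)
        twice, report2 = curate_fecundity_table(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )
        assert report.input_rows == sum(report.removed.values()) + report.retained_rows
        assert sum(report2.removed.values()) == 0

    def test_supplementary_vocabulary_accepted(self):
        df = pd.DataFrame(
            {
                "Species": ["A"] * 12,
                "Mass_g": 100.0,
                "Fecundity._n.Of.Eggs": 1e4,
                "Latitude": -12.0,
                "Year": 2000,
            }
        )
        curated, _ = curate_fecundity_table(df)
        assert len(curated) == 12
        assert (curated["abs_lat"] == 12.0).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            curate_fecundity_table(pd.DataFrame({"species": ["A"], "year": [2000]}))


def _balanced_fecundity(n_species=12, n_per=20, sd_int=0.0, sd_slope=0.0, sigma=0.0, seed=3):
    rng = np.random.default_rng(seed)
    c, d, rs_a, rs_b = 5.39, -0.02, 1.00, 0.004
    rows = []
    for i in range(n_species):
        lat = (i / (n_species - 1)) * 60.0
        u = rng.normal(0, sd_int) if sd_int else 0.0
        v = rng.normal(0, sd_slope) if sd_slope else 0.0
        ln_m = np.linspace(np.log(50), np.log(5000), n_per)
        ln_f = c + d * lat + (rs_a + rs_b * lat + v) * ln_m + u + rng.normal(0, sigma, n_per)
        for lm, lf in zip(ln_m, ln_f):
            rows.append(
                {"species": f"sp{i}", "mass_g": np.exp(lm), "fecundity": np.exp(lf),
                 "abs_lat": lat, "year": 2000}
            )
    return pd.DataFrame(rows)


class TestFecundityModel:
    def test_noiseless_exact_recovery_and_estimator_agreement(self):
        df = _balanced_fecundity()
        mixed = FecundityModel.from_dataframe(df).fit(method="two_stage")
        for got, want in zip(
            (mixed.coefs.c, mixed.coefs.d, mixed.coefs.rs_a, mixed.coefs.rs_b),
            (5.39, -0.02, 1.00, 0.004),
        ):
            assert got == pytest.approx(want, abs=1e-6)

    def test_seeded_recovery_within_two_se(self):
        from fishlhopt.synth import default_truth, simulate_fecundity_observations

        df, _ = simulate_fecundity_observations(default_truth(), 40, 30, seed=11)
        res = FecundityModel.from_dataframe(df).fit()
        truth = {"c": 5.39, "d": -0.02, "rs_a": 1.00, "rs_b": 0.004}
        coefs = res.coefs
        for name, want in truth.items():
            got = getattr(coefs, name)
            assert abs(got - want) < 2.5 * res.bse[name], (name, got, want, res.bse[name])

    def test_isometric_null_recovered(self):
        df = _balanced_fecundity(sigma=0.1, seed=9)
        # rebuild with rs_b = 0, d = 0, rs_a = 1
        rng = np.random.default_rng(9)
        df["fecundity"] = np.exp(
            5.39 + 1.0 * np.log(df["mass_g"]) + rng.normal(0, 0.1, len(df))
        )
        res = FecundityModel.from_dataframe(df).fit()
        assert abs(res.coefs.rs_b) < 2.5 * res.bse["rs_b"]

    def test_per_population_contrast_matches_construction(self):
        # with a positive latitude-exponent interaction, the higher-latitude
        # population of the same species shows the larger mass slope
        df = _balanced_fecundity(sigma=0.0)
        lo = df[df["abs_lat"] < 10]
        hi = df[df["abs_lat"] > 50]
        slope = lambda g: np.polyfit(np.log(g["mass_g"]), np.log(g["fecundity"]), 1)[0]
        assert slope(hi) > slope(lo)

    def test_brownian_tree_route_runs(self):
        from fishlhopt.synth import default_truth, simulate_fecundity_observations

        df, tree = simulate_fecundity_observations(default_truth(), 12, 15, tree=True, seed=5)
        res = FecundityModel.from_dataframe(df, tree=tree).fit()
        assert res.method == "two_stage"
        assert res.coefs.rs_a == pytest.approx(1.0, abs=0.3)

    def test_single_species_rejected(self):
        df = _balanced_fecundity(n_species=12).query("species == 'sp0'")
        with pytest.raises(ValueError):
            FecundityModel.from_dataframe(df)


class TestPredictFecundity:
    def test_published_worked_examples(self):
        coefs = literature_fecundity_coefs()
        assert predict_fecundity(coefs, 10_000.0, 0.0) == pytest.approx(2.19e6, rel=0.01)
        assert predict_fecundity(coefs, 20_000.0, 0.0) == pytest.approx(
            np.exp(5.39) * 20_000.0, rel=1e-12
        )

    def test_isometry_doubles(self):
        from fishlhopt.calibrate import FecundityModelCoefs

        coefs = FecundityModelCoefs(c=2.0, d=0.0, rs_a=1.0, rs_b=0.0)
        assert predict_fecundity(coefs, 200.0, 30.0) == pytest.approx(
            2 * predict_fecundity(coefs, 100.0, 30.0)
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            predict_fecundity(literature_fecundity_coefs(), 0.0, 10.0)


class TestA50:
    def test_published_intercept(self):
        assert literature_a50().value(0.0) == pytest.approx(0.76, rel=0.01)

    def test_noiseless_exact_recovery(self):
        lat = np.linspace(5, 70, 25)
        df = pd.DataFrame({"abs_lat": lat, "a50": np.exp(-0.28 + 0.034 * lat)})
        res = fit_a50(df)
        assert res.a == pytest.approx(-0.28, abs=1e-10)
        assert res.b_lat == pytest.approx(0.034, abs=1e-12)

    def test_direct_only_filters_records(self):
        lat = np.linspace(5, 70, 30)
        df = pd.DataFrame(
            {
                "abs_lat": lat,
                "a50": np.exp(-0.28 + 0.034 * lat),
                "direct": [True] * 20 + [False] * 10,
            }
        )
        assert fit_a50(df, direct_only=True).nobs == 20
        assert fit_a50(df, direct_only=False).nobs == 30


class TestAggregateMortality:
    def test_same_reference_rows_averaged(self):
        df = pd.DataFrame(
            {
                "species": ["A", "A", "B"],
                "reference": ["r1", "r1", "r1"],
                "latitude": [10.0, 20.0, 5.0],
                "M": [0.4, 0.6, 0.3],
            }
        )
        out = aggregate_mortality(df)
        row = out[out["species"] == "A"].iloc[0]
        assert row["M"] == pytest.approx(0.5)
        assert row["latitude"] == pytest.approx(15.0)
        assert len(out) == 2  # singleton passes through

    def test_group_structure_collapse(self):
        # 131 records built over 82 species x reference groups collapse to 82
        rng = np.random.default_rng(8)
        groups = [(f"sp{i}", f"ref{i % 40}") for i in range(82)]
        rows = [
            {"species": sp, "reference": ref,
             "latitude": rng.uniform(0, 70), "M": rng.uniform(0.1, 1.0)}
            for sp, ref in groups
        ]
        for sp, ref in groups[:49]:  # duplicates within existing groups
            rows.append({"species": sp, "reference": ref,
                         "latitude": rng.uniform(0, 70), "M": rng.uniform(0.1, 1.0)})
        df = pd.DataFrame(rows)
        assert len(df) == 131
        out = aggregate_mortality(df)
        assert len(out) == 82

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mortality(pd.DataFrame({"species": ["A"], "M": [0.5]}))
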