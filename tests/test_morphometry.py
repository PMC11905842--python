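"""Volume aggregation and robust statistical models."""

import numpy as np
import pandas as pd
import pytest

from pmmorph.core import LabelVolume, VoxelGrid
from pmmorph.morphometry import (
    aggregate_volumes,
    average_aggregates,
    cohort_tests,
    fit_age_score_band,
    fit_morphometry_model,
    fit_robust_linear,
)
from pmmorph.phantom import CohortSpec, make_cohort


class TestAggregateVolumes:
    def test_cerebellum_two_voxels(self, phantom_sample):
        grid = VoxelGrid((4, 4, 4), (0.5, 0.5, 0.5))
        lab = np.zeros(grid.dims, np.int32)
        lab[0, 0, 0] = 7
        lab[1, 1, 1] = 8
        _, agg = aggregate_volumes(LabelVolume(grid, lab), phantom_sample.label_table)
        assert agg["cerebellum"] == pytest.approx(0.25)  # 2 voxels x 0.125 mm3

    def test_deep_gm_sum_is_exact(self, phantom_sample):
        per_label, agg = aggregate_volumes(phantom_sample.truth_parcellation,
                                           phantom_sample.label_table)
        deep = per_label[per_label["region"].isin([10, 11, 12, 13, 17, 18, 26])]
        assert agg["deep_gm"] == pytest.approx(deep["volume_mm3"].sum(), rel=1e-12)
        assert agg["total_brain"] == pytest.approx(per_label["volume_mm3"].sum())

    def test_missing_hippocampus_reported_as_none(self, phantom_sample):
        parc = phantom_sample.truth_parcellation
        lab = np.where(parc.labels == 17, 0, parc.labels)
        _, agg = aggregate_volumes(parc.with_labels(lab), phantom_sample.label_table)
        assert agg["hippocampus"] is None
        assert agg["deep_gm"] is None  # 17 is part of the deep GM aggregate too

    def test_two_scans_averaged(self):
        a = {"deep_gm": 100.0, "hippocampus": 10.0}
        b = {"deep_gm": 200.0, "hippocampus": None}
        out = average_aggregates([a, b])
        assert out["deep_gm"] == 150.0
        assert out["hippocampus"] is None


class TestRobustLinear:
    def test_noiseless_recovery(self, rng):
        n = 60
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["y"] = 2.0 + 3.0 * df["x1"] - 1.5 * df["x2"]
        fit = fit_robust_linear(df, "y", ["x1", "x2"])
        np.testing.assert_allclose(fit.params[["const", "x1", "x2"]],
                                   [2.0, 3.0, -1.5], atol=1e-8)
        assert (fit.pvalues <= 1.0).all() and (fit.pvalues >= 0.0).all()

    def test_huber_beats_ols_under_gross_outliers(self):
        """Median coefficient error over replicates: Huber < OLS at 10% outliers."""
        errs_h, errs_o = [], []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            n = 80
            x = rng.normal(size=n)
            y = 1.0 + 2.0 * x + 0.3 * rng.standard_normal(n)
            out = rng.random(n) < 0.10
            y[out] += rng.choice([-1, 1], size=out.sum()) * 30.0
            df = pd.DataFrame({"x": x, "y": y})
            fit = fit_robust_linear(df, "y", ["x"])
            X = np.column_stack([np.ones(n), x])
            beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
            errs_h.append(abs(fit.params["x"] - 2.0))
            errs_o.append(abs(beta_ols[1] - 2.0))
        assert np.mean(errs_h) < np.mean(errs_o)

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"x1": [1.0] * 10, "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="singular"):
            fit_robust_linear(df, "y", ["x1"])  # x1 collinear with intercept

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="too small"):
            fit_robust_linear(df, "y", ["x"])


class TestMorphometryModel:
    def test_generator_coefficients_recovered_within_2se(self):
        spec = CohortSpec(n_donors=200, seed=3)
        records, volumes = make_cohort(spec)
        fit = fit_morphometry_model(volumes, records, "brain")
        gen = spec.region_models["brain"]
        for name, key in [("const", "intercept"), ("sexF", "sexF"),
                          ("invivo", "invivo"), ("age", "age")]:
            assert abs(fit.params[name] - gen[key]) < 2 * fit.bse[name], name

    def test_invivo_rows_inherit_diagnosis(self):
        records, volumes = make_cohort(CohortSpec(n_donors=80, seed=5))
        fit = fit_morphometry_model(volumes, records, "deep_gm")
        assert fit.nobs == len(volumes)


class TestAgeScoreBand:
    def test_noiseless_quadratic_exact(self):
        s = np.tile(np.arange(15.0), 10)
        age = 60.0 + 3.0 * s - 0.1 * s ** 2
        records = pd.DataFrame({"age_death": age, "sum_scores": s})
        fit = fit_age_score_band(records)
        np.testing.assert_allclose(
            fit.age_fit.params[["const", "s", "s2"]], [60.0, 3.0, -0.1], atol=1e-6)
        # error fit is ~0 everywhere
        lo, hi = fit.band(np.linspace(0, 14, 20))
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-5)

    def test_constant_noise_gives_flat_error_fit(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 15, size=200).astype(float)
        age = 60.0 + 3.0 * s - 0.1 * s ** 2 + rng.normal(0, 5.0, 200)
        records = pd.DataFrame({"age_death": age, "sum_scores": s})
        fit = fit_age_score_band(records)
        lo, hi = fit.band(np.linspace(0, 14, 15))
        width = hi - lo
        assert width.min() > 0
        assert width.max() / width.min() < 2.5  # near-constant spread

    def test_inverted_u_sign_recovered(self):
        rng = np.random.default_rng(1)
        s = rng.integers(0, 15, size=200).astype(float)
        age = 55.0 + 4.0 * s - 0.2 * s ** 2 + rng.normal(0, 4.0, 200)
        records = pd.DataFrame({"age_death": age, "sum_scores": s})
        fit = fit_age_score_band(records)
        assert fit.age_fit.params["s2"] < 0

    def test_band_contains_prediction(self):
        records, _ = make_cohort(CohortSpec(n_donors=120, seed=9))
        fit = fit_age_score_band(records)
        s = np.linspace(0, 14, 29)
        lo, hi = fit.band(s)
        mid = fit.predicted(s)
        assert np.all(lo <= mid + 1e-9) and np.all(mid <= hi + 1e-9)

    def test_constant_scores_rejected(self):
        records = pd.DataFrame({"age_death": [70.0] * 10, "sum_scores": [5.0] * 10})
        with pytest.raises(ValueError, match="singular|constant"):
            fit_age_score_band(records)


class TestCohortTests:
    def test_identical_groups_welch_p_one(self):
        records = pd.DataFrame({
            "sex": ["M"] * 10 + ["F"] * 10,
            "age_death": list(range(10)) * 2,
            "sum_scores": [5.0] * 20, "thal": [3] * 20, "braak": [4] * 20,
            "cerad": [2] * 20, "AD": [0] * 20, "FTD": [0] * 20, "OD": [0] * 20,
            "VD": [0] * 20, "M": [0] * 20,
        })
        out = cohort_tests(records, welch_columns=("age_death",))
        welch = out[out["test"] == "welch:age_death"].iloc[0]
        assert welch["p_value"] == pytest.approx(1.0)

    def test_balanced_contingency_fisher(self):
        from scipy import stats

        odds, p = stats.fisher_exact([[10, 10], [10, 10]])
        assert odds == 1.0 and p == 1.0

    def test_degenerate_group_flagged(self):
        records = pd.DataFrame({
            "sex": ["M"] * 12, "age_death": np.arange(12.0),
            "AD": [1] * 6 + [0] * 6, "FTD": [0] * 12, "OD": [0] * 12,
            "VD": [0] * 12, "M": [0] * 12,
        })
        out = cohort_tests(records, welch_columns=("age_death",))
        assert out[out["test"] == "welch:age_death"].iloc[0]["note"] == "degenerate group"
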