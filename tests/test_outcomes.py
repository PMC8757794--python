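"""Occlusion Logit, TTO ANCOVA, diagnostics and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fdmesh import (
    fit_occlusion_logit,
    fit_tto_ancova,
    residual_diagnostics,
    tto_summary,
    validate_cohort,
)
from fdmesh.errors import CohortSchemaError
from fdmesh.synthetic import default_truth, generate_cohort


def _toy_binary(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(0.4 + 0.8 * x)).astype(int)
    return pd.DataFrame({"occluded": y, "x": x})


def _null_ancova_table(n=120, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "occluded": np.ones(n, dtype=int),
        "tto_months": rng.normal(7.0, 1.0, n),
        "fu_months": np.full(n, 12.0),
        "brand_label": rng.choice(["Derivo", "P64", "Pipeline", "Surpass"], n),
        "age": rng.uniform(30, 75, n),
        "porosity_mean": rng.normal(0.72, 0.05, n),
        "angle_mean": rng.normal(101.0, 8.0, n),
        "expansion_mean": rng.normal(87.0, 6.0, n),
        "maai": rng.normal(0.0, 1.9, n),
    })


class TestLogit:
    def test_matches_brute_force_likelihood_maximizer(self):
        """Newton fit agrees with a refined grid search of the log-likelihood."""
        df = _toy_binary()
        fit = fit_occlusion_logit(df, terms=("x",))
        y = df["occluded"].to_numpy()
        x = df["x"].to_numpy()

        def llf(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        lo = np.array([-4.0, -4.0])
        hi = np.array([4.0, 4.0])
        for _ in range(6):  # coarse-to-fine grid, final step < 1e-3
            g0 = np.linspace(lo[0], hi[0], 41)
            g1 = np.linspace(lo[1], hi[1], 41)
            vals = np.array([[llf(a, b) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            step0, step1 = g0[1] - g0[0], g1[1] - g1[0]
            lo = np.array([g0[i] - step0, g1[j] - step1])
            hi = np.array([g0[i] + step0, g1[j] + step1])
        best = 0.5 * (lo + hi)
        assert fit.params["Intercept"] == pytest.approx(best[0], abs=1e-3)
        assert fit.params["x"] == pytest.approx(best[1], abs=1e-3)

    def test_single_class_outcome_rejected(self):
        df = _toy_binary()
        df["occluded"] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_occlusion_logit(df, terms=("x",))

    def test_constant_covariate_is_an_error_not_a_silent_nan(self):
        df = _toy_binary()
        df["z"] = 0.0
        with pytest.raises(ValueError, match="'z'"):
            fit_occlusion_logit(df, terms=("x", "z"))

    def test_separation_is_flagged_not_raised(self):
        n = 60
        rng = np.random.default_rng(2)
        x = rng.normal(size=n)
        df = pd.DataFrame({"occluded": (x > 0).astype(int), "x": x})
        fit = fit_occlusion_logit(df, terms=("x",))
        assert fit.separation

    def test_small_tables_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_occlusion_logit(_toy_binary(n=6), terms=("x",))


class TestAncova:
    def test_covariate_order_changes_decomposition_not_fit(self):
        tab = _null_ancova_table(seed=3)
        a = fit_tto_ancova(tab, ("porosity_mean", "angle_mean", "expansion_mean", "maai"))
        b = fit_tto_ancova(tab, ("maai", "expansion_mean", "angle_mean", "porosity_mean"))
        np.testing.assert_allclose(a.fitted, b.fitted, atol=1e-10)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)
        ssa = a.sequential.set_index("term")["ss"]
        ssb = b.sequential.set_index("term")["ss"]
        assert not np.allclose(ssa["porosity_mean"], ssb["porosity_mean"])
        assert ssa.sum() == pytest.approx(ssb.sum(), rel=1e-9)  # same total SS

    def test_sequential_ss_partitions_total_ss(self):
        tab = _null_ancova_table(seed=4)
        fit = fit_tto_ancova(tab)
        y = tab["tto_months"].to_numpy()
        total = float(np.sum((y - y.mean()) ** 2))
        assert fit.sequential["ss"].sum() == pytest.approx(total, rel=1e-9)
        assert (fit.sequential["ss"].to_numpy() >= -1e-9).all()
        assert 0.0 <= fit.r_squared <= 1.0

    def test_occluded_subset_filter(self):
        tab = _null_ancova_table(seed=5)
        tab.loc[:20, "occluded"] = 0
        fit = fit_tto_ancova(tab)
        assert fit.nobs == int((tab["occluded"] == 1).sum())

    def test_empty_occluded_subset_rejected(self):
        tab = _null_ancova_table(seed=6)
        tab["occluded"] = 0
        with pytest.raises(ValueError, match="no occluded rows"):
            fit_tto_ancova(tab)

    def test_thin_brand_level_named(self):
        tab = _null_ancova_table(seed=7)
        tab["brand_label"] = "Pipeline"
        tab.loc[0, "brand_label"] = "Derivo"
        with pytest.raises(ValueError, match="Derivo"):
            fit_tto_ancova(tab)

    @pytest.mark.parametrize("handling,term_cols", [
        ("linear", 1), ("quadratic", 2), ("tertiles", 2),
    ])
    def test_age_handling_options(self, handling, term_cols):
        fit = fit_tto_ancova(_null_ancova_table(seed=8), age_handling=handling)
        age_row = fit.sequential.set_index("term").loc["age"]
        assert int(age_row["df"]) == term_cols


class TestDiagnostics:
    def test_identical_residual_spreads_give_zero_statistic(self):
        tab = _null_ancova_table(n=120, seed=9)
        fit = fit_tto_ancova(tab)
        # same residual multiset in every group -> between-group spread 0
        block = np.tile(np.linspace(-1.0, 1.0, 30), 4)
        fit.residuals = block
        fit.data = fit.data.iloc[:120].copy()
        fit.data["brand_label"] = np.repeat(["Derivo", "P64", "Pipeline", "Surpass"], 30)
        fit.data.index = range(120)
        diag = residual_diagnostics(fit, "brand_label")
        assert diag["levene"][0] == pytest.approx(0.0, abs=1e-12)

    def test_scaled_group_is_detected(self):
        rng = np.random.default_rng(10)
        tab = _null_ancova_table(n=150, seed=10)
        fit = fit_tto_ancova(tab)
        resid = rng.normal(size=fit.residuals.shape[0])
        grp = fit.data["brand_label"].to_numpy()
        resid[grp == "Pipeline"] *= 3.0
        fit.residuals = resid
        diag = residual_diagnostics(fit, "brand_label")
        assert diag["levene"][1] < 0.01

    def test_singleton_group_excluded_with_warning(self):
        tab = _null_ancova_table(n=150, seed=11)
        fit = fit_tto_ancova(tab)
        fit.data = fit.data.copy()
        labels = fit.data["brand_label"].copy()
        labels.iloc[:] = np.where(np.arange(len(labels)) == 0, "P64", "Pipeline")
        fit.data["brand_label"] = labels
        with pytest.warns(UserWarning, match="excluded"):
            diag = residual_diagnostics(fit, "brand_label")
        assert diag["excluded_groups"] == ["P64"]

    def test_too_few_residuals_rejected(self):
        tab = _null_ancova_table(n=120, seed=12)
        fit = fit_tto_ancova(tab)
        fit.residuals = fit.residuals[:5]
        with pytest.raises(ValueError, match="at least 8"):
            residual_diagnostics(fit)


class TestTtoSummary:
    def test_hand_arithmetic(self):
        tab = pd.DataFrame({"occluded": [1, 1, 0],
                            "tto_months": [6.0, 8.0, np.nan]})
        mean, se, n = tto_summary(tab)
        assert (mean, se, n) == (7.0, 1.0, 2)

    def test_constant_tto_has_zero_se(self):
        tab = pd.DataFrame({"occluded": [1] * 5, "tto_months": [7.0] * 5})
        assert tto_summary(tab)[1] == 0.0

    def test_too_few_occluded_rejected(self):
        tab = pd.DataFrame({"occluded": [1, 0], "tto_months": [6.0, np.nan]})
        with pytest.raises(ValueError, match="at least 2"):
            tto_summary(tab)


class TestCohortSchema:
    def test_generated_cohort_passes_validation(self):
        tab, _ = generate_cohort(default_truth(), 64, seed=5)
        validate_cohort(tab)

    def test_violations_name_the_row(self):
        tab, _ = generate_cohort(default_truth(), 64, seed=5)
        bad = tab.copy()
        bad.loc[2, "fu_months"] = 30.0
        with pytest.raises(CohortSchemaError, match="row 3"):
            validate_cohort(bad)
        bad = tab.copy()
        bad.loc[0, "brand_label"] = "Acme"
        with pytest.raises(CohortSchemaError, match="row 1"):
            validate_cohort(bad)
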