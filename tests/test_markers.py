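"""Marker panel preprocessing, differential abundance, adjustment, scores."""

import numpy as np
import pandas as pd
import pytest

import dsimmune as d
from dsimmune.markers import (
    MarkerDifferentialAbundance,
    MarkerPanel,
    adjust_covariates,
    cytokine_score,
    exclude_outliers_per_group,
    preprocess_panel,
)


def _wells(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "analyte", "plate", "well", "concentration", "range_status"],
    )


class TestPreprocess:
    def test_duplicate_wells_averaged(self):
        panel = MarkerPanel(
            _wells(
                [
                    ("s1", "A", "p1", "w1", 100.0, "in_range"),
                    ("s1", "A", "p1", "w2", 110.0, "in_range"),
                ]
            )
        )
        out = preprocess_panel(panel)
        assert out.to_matrix().loc["A", "s1"] == pytest.approx(105.0)

    def test_below_range_imputed_with_plate_minimum(self):
        panel = MarkerPanel(
            _wells(
                [
                    ("s1", "A", "p1", "w1", 2.5, "in_range"),
                    ("s2", "A", "p1", "w2", 8.0, "in_range"),
                    ("s3", "A", "p1", "w3", np.nan, "below_range"),
                    ("s4", "A", "p2", "w4", 1.0, "in_range"),
                ]
            )
        )
        out = preprocess_panel(panel)
        # plate p1 in-range minimum is 2.5, not the global minimum 1.0
        assert out.to_matrix().loc["A", "s3"] == pytest.approx(2.5)

    def test_above_range_imputed_with_plate_maximum(self):
        panel = MarkerPanel(
            _wells(
                [
                    ("s1", "A", "p1", "w1", 2.5, "in_range"),
                    ("s2", "A", "p1", "w2", 8.0, "in_range"),
                    ("s3", "A", "p1", "w3", np.nan, "above_range"),
                ]
            )
        )
        assert preprocess_panel(panel).to_matrix().loc["A", "s3"] == pytest.approx(8.0)

    def test_flag_rule_over_ten_percent(self):
        rows = [
            (f"s{i}", "A", "p1", f"w{i}", np.nan if i < 3 else 5.0,
             "below_range" if i < 3 else "in_range")
            for i in range(20)
        ]
        out = preprocess_panel(MarkerPanel(_wells(rows)))
        assert bool(out.analyte_flags["A"])  # 3/20 = 15% > 10%
        assert out.out_of_range_fraction["A"] == pytest.approx(0.15)

    def test_flag_rule_under_threshold(self):
        rows = [
            (f"s{i}", "A", "p1", f"w{i}", np.nan if i < 1 else 5.0,
             "below_range" if i < 1 else "in_range")
            for i in range(20)
        ]
        out = preprocess_panel(MarkerPanel(_wells(rows)))
        assert not bool(out.analyte_flags["A"])  # 1/20 = 5%

    def test_idempotent(self, medium_cohort):
        panel = d.cohort.simulate_marker_panel(
            medium_cohort, d.EffectSpec(), n_analytes=6, seed=31,
            out_of_range_frac=0.08,
        )
        once = preprocess_panel(panel)
        twice = preprocess_panel(once)
        pd.testing.assert_frame_equal(once.wells, twice.wells)
        pd.testing.assert_series_equal(once.analyte_flags, twice.analyte_flags)

    def test_imputation_impossible_error(self):
        panel = MarkerPanel(
            _wells([("s1", "A", "p1", "w1", np.nan, "below_range")])
        )
        with pytest.raises(ValueError, match="imputation impossible"):
            preprocess_panel(panel)


class TestOutlierExclusion:
    def test_extreme_value_excluded_within_its_group_only(self):
        samples = [f"s{i}" for i in range(20)]
        groups = pd.Series(["T21"] * 10 + ["D21"] * 10, index=samples)
        vals = np.ones((1, 20)) * 5.0
        vals[0, :10] = list(range(1, 10)) + [100.0]
        mat = pd.DataFrame(vals, index=["A"], columns=samples)
        out, log = exclude_outliers_per_group(mat, groups)
        assert np.isnan(out.loc["A", "s9"])
        assert out.loc["A", samples[10:]].notna().all()
        assert len(log) == 1 and log.loc[0, "group"] == "T21"

    def test_no_outliers_no_change(self, rng):
        samples = [f"s{i}" for i in range(20)]
        groups = pd.Series(["T21"] * 10 + ["D21"] * 10, index=samples)
        mat = pd.DataFrame(
            rng.uniform(4, 6, (3, 20)), index=list("ABC"), columns=samples
        )
        out, log = exclude_outliers_per_group(mat, groups)
        pd.testing.assert_frame_equal(out, mat)
        assert log.empty


class TestDifferentialAbundance:
    def test_single_source_equals_ols(self, rng):
        n = 60
        samples = [f"s{i}" for i in range(n)]
        part = pd.DataFrame(
            {
                "karyotype": ["T21"] * 40 + ["D21"] * 20,
                "age": rng.uniform(5, 50, n),
                "sex": rng.choice(["Female", "Male"], n),
                "source": "Site1",
            },
            index=samples,
        )
        y = 5 + 0.8 * (part["karyotype"] == "T21") + 0.01 * part["age"]
        mat = pd.DataFrame(
            [np.power(2.0, y + rng.normal(0, 0.3, n))], index=["A"], columns=samples
        )
        res = MarkerDifferentialAbundance(mat, part).fit()
        assert res.table.loc["A", "method"] == "ols"
        import statsmodels.formula.api as smf

        df = part.assign(y=np.log2(mat.loc["A"]))
        ols = smf.ols(
            "y ~ C(karyotype, Treatment('D21')) + age + sex", df
        ).fit()
        assert res.table.loc["A", "log2_fc"] == pytest.approx(
            ols.params["C(karyotype, Treatment('D21'))[T.T21]"]
        )

    def test_injected_log2_shift_recovered(self):
        errs = []
        for seed in range(5):
            part = d.cohort.simulate_participants(
                d.CohortSpec(n_t21=200, n_d21=100, seed=seed)
            )
            panel = d.cohort.simulate_marker_panel(
                part,
                d.EffectSpec(elevated_analytes={"TNF-a": 1.0}),
                n_analytes=4,
                seed=seed + 100,
                noise_sd=1.0,
            )
            mat = preprocess_panel(panel).to_matrix()
            res = MarkerDifferentialAbundance(mat, part).fit()
            errs.append(res.table.loc["TNF-a", "log2_fc"] - 1.0)
        assert abs(np.mean(errs)) < 0.15

    def test_summary_mentions_model(self, medium_cohort):
        panel = d.cohort.simulate_marker_panel(
            medium_cohort, d.EffectSpec(), n_analytes=3, seed=32
        )
        res = MarkerDifferentialAbundance(
            preprocess_panel(panel).to_matrix(), medium_cohort
        ).fit()
        s = res.summary()
        assert "log2(conc) ~ karyotype" in s and "random intercept" in s


class TestAdjustCovariates:
    def test_constant_covariate_leaves_values_unchanged(self, rng):
        samples = [f"s{i}" for i in range(30)]
        part = pd.DataFrame(
            {"karyotype": ["T21"] * 15 + ["D21"] * 15, "age": 10.0},
            index=samples,
        )
        mat = pd.DataFrame(rng.normal(5, 1, (3, 30)), index=list("ABC"), columns=samples)
        adj = adjust_covariates(mat, part, covariates=("age",), keep="karyotype")
        pd.testing.assert_frame_equal(adj.values, mat, atol=1e-9, check_exact=False)

    def test_age_slope_removed(self, rng):
        n = 200
        samples = [f"s{i}" for i in range(n)]
        age = rng.uniform(1, 60, n)
        part = pd.DataFrame(
            {"karyotype": rng.choice(["T21", "D21"], n), "age": age}, index=samples
        )
        y = 3 + 0.05 * age + rng.normal(0, 0.2, n)
        mat = pd.DataFrame([y], index=["A"], columns=samples)
        adj = adjust_covariates(mat, part, covariates=("age",), keep="karyotype")
        slope = np.polyfit(age, adj.values.loc["A"].values, 1)[0]
        assert abs(slope) < 0.005

    def test_noiseless_residualization_is_exact(self):
        n = 50
        samples = [f"s{i}" for i in range(n)]
        age = np.linspace(1, 50, n)
        part = pd.DataFrame({"karyotype": ["T21"] * n, "age": age}, index=samples)
        mat = pd.DataFrame([2 + 0.1 * age], index=["A"], columns=samples)
        adj = adjust_covariates(mat, part, covariates=("age",), keep=None)
        slope = np.polyfit(age, adj.values.loc["A"].values, 1)[0]
        assert abs(slope) < 1e-6

    def test_group_difference_preserved_under_balanced_design(self, rng):
        n = 400
        samples = [f"s{i}" for i in range(n)]
        grp = np.tile(["T21", "D21"], n // 2)
        age = np.tile(rng.uniform(5, 50, n // 2), 2)  # identical age per pair
        part = pd.DataFrame({"karyotype": grp, "age": age}, index=samples)
        y = 5 + 1.0 * (grp == "T21") + 0.03 * age + rng.normal(0, 0.1, n)
        mat = pd.DataFrame([y], index=["A"], columns=samples)
        adj = adjust_covariates(mat, part, covariates=("age",), keep="karyotype")
        diff = (
            adj.values.loc["A", part["karyotype"] == "T21"].mean()
            - adj.values.loc["A", part["karyotype"] == "D21"].mean()
        )
        assert diff == pytest.approx(1.0, abs=0.05)

    def test_collinear_covariates_rejected(self, rng):
        n = 20
        samples = [f"s{i}" for i in range(n)]
        age = rng.uniform(1, 50, n)
        part = pd.DataFrame(
            {"karyotype": ["T21"] * n, "age": age, "age2": 2 * age}, index=samples
        )
        mat = pd.DataFrame([age], index=["A"], columns=samples)
        with pytest.raises(ValueError, match="collinear"):
            adjust_covariates(mat, part, covariates=("age", "age2"), keep=None)


class TestCytokineScore:
    @staticmethod
    def _matrix(rng, n=40):
        samples = [f"s{i}" for i in range(n)]
        return pd.DataFrame(
            rng.normal(5, 1, (4, n)),
            index=list(d.markers.CYTOKINE_SCORE_COMPONENTS),
            columns=samples,
        )

    def test_sample_at_reference_mean_scores_zero(self, rng):
        mat = self._matrix(rng)
        ref = list(mat.columns[:20])
        mat["probe"] = mat[ref].mean(axis=1)
        out = cytokine_score(mat, reference=ref)
        assert out.scores["probe"] == pytest.approx(0.0, abs=1e-9)

    def test_one_sd_shift_on_each_component_scores_four(self, rng):
        mat = self._matrix(rng)
        ref = list(mat.columns[:20])
        mu = mat[ref].mean(axis=1)
        sd = mat[ref].std(axis=1, ddof=1)
        mat["probe"] = mu + sd
        out = cytokine_score(mat, reference=ref)
        assert out.scores["probe"] == pytest.approx(4.0, abs=1e-9)

    def test_reference_population_mean_is_zero(self, rng):
        mat = self._matrix(rng)
        out = cytokine_score(mat, reference="self")
        assert out.scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance_per_analyte(self, rng):
        mat = self._matrix(rng)
        scale = pd.Series([2.0, 0.5, 3.0, 1.5], index=mat.index)
        shift = pd.Series([1.0, -2.0, 0.0, 4.0], index=mat.index)
        rescaled = mat.mul(scale, axis=0).add(shift, axis=0)
        a = cytokine_score(mat, reference="self").scores
        b = cytokine_score(rescaled, reference="self").scores
        pd.testing.assert_series_equal(a, b, atol=1e-9, check_exact=False)

    def test_missing_component_listed(self, rng):
        mat = self._matrix(rng).drop(index=["CRP"])
        with pytest.raises(ValueError, match="CRP"):
            cytokine_score(mat)

    def test_degenerate_reference_rejected(self):
        mat = pd.DataFrame(
            np.ones((4, 6)),
            index=list(d.markers.CYTOKINE_SCORE_COMPONENTS),
            columns=[f"s{i}" for i in range(6)],
        )
        with pytest.raises(ValueError, match="degenerate"):
            cytokine_score(mat, reference="self")
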