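"""Autoantibody pipeline: MAD normalization, positivity, over-representation."""

import numpy as np
import pandas as pd
import pytest

import dsimmune as d
from dsimmune.autoantibody import (
    AntigenReactivityMatrix,
    ana_call,
    call_positivity,
    mad_transform,
    positivity_burden,
    qc_filter,
    tpo_index,
    tpo_threshold,
)
from dsimmune.autoantibody import test_overrepresentation as overrepresentation_screen
from dsimmune.autoantibody import (
    test_phenotype_associations as phenotype_association_screen,
)
from oracles import quantile_oracle


def _matrix(values, samples=None, beads=None):
    mfi = pd.DataFrame(values)
    if samples is not None:
        mfi.columns = samples
    bc = pd.DataFrame(beads, index=mfi.index, columns=mfi.columns) if beads is not None else None
    return AntigenReactivityMatrix(mfi=mfi, bead_counts=bc)


class TestQcFilter:
    def test_zero_min_beads_is_identity(self, rng):
        m = _matrix(rng.uniform(1, 100, (5, 4)), beads=np.full((5, 4), 50))
        out, log = qc_filter(m, min_beads=0)
        pd.testing.assert_frame_equal(out.mfi, m.mfi)
        assert log["n_reactions_masked"] == 0

    def test_low_bead_reaction_masked(self, rng):
        beads = np.full((3, 4), 50.0)
        beads[1, 2] = 3
        m = _matrix(rng.uniform(1, 100, (3, 4)), beads=beads)
        out, log = qc_filter(m, min_beads=20)
        assert np.isnan(out.mfi.iloc[1, 2])
        assert log["n_reactions_masked"] == 1

    def test_mostly_missing_antigen_dropped(self, rng):
        beads = np.full((3, 10), 50.0)
        beads[0, :6] = 1  # 60% missing for antigen 0
        m = _matrix(rng.uniform(1, 100, (3, 10)), beads=beads)
        out, log = qc_filter(m, min_beads=20, max_missing_frac=0.5)
        assert list(log["dropped_antigens"]) == [0]
        assert out.mfi.shape[0] == 2


class TestMadTransform:
    def test_hand_worked_example(self):
        m = _matrix({"s1": [10.0, 20.0, 30.0]})
        out = mad_transform(m)
        np.testing.assert_allclose(out.mad_scores["s1"].values, [-1.0, 0.0, 1.0])

    def test_constant_sample_excluded(self):
        m = _matrix({"s1": [10.0, 20.0, 30.0], "s2": [5.0, 5.0, 5.0]})
        out = mad_transform(m)
        assert out.excluded_samples == ["s2"]
        assert list(out.mad_scores.columns) == ["s1"]

    def test_per_sample_identities(self, rng):
        m = _matrix(rng.lognormal(3, 1, (50, 20)))
        out = mad_transform(m)
        med = out.mad_scores.median(axis=0)
        mad = (out.mad_scores - med).abs().median(axis=0)
        np.testing.assert_allclose(med.values, 0.0, atol=1e-9)
        np.testing.assert_allclose(mad.values, 1.0, atol=1e-9)

    def test_affine_invariance(self, rng):
        vals = rng.lognormal(3, 1, (30, 5))
        a = mad_transform(_matrix(vals)).mad_scores
        b = mad_transform(_matrix(vals * 3.5 + 7.0)).mad_scores
        pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-9)

    def test_missing_propagates(self, rng):
        vals = rng.lognormal(3, 1, (30, 3))
        vals[4, 1] = np.nan
        out = mad_transform(_matrix(vals))
        assert np.isnan(out.mad_scores.iloc[4, 1])


class TestCallPositivity:
    def test_threshold_interpolation(self):
        # controls 0..9: 90th percentile = 8.1 by linear interpolation
        scores = pd.DataFrame(
            [list(range(10)) + [9.0, 5.0]],
            index=["a1"],
            columns=[f"c{i}" for i in range(10)] + ["t1", "t2"],
        ).astype(float)
        out = call_positivity(
            d.ReactivityScoreMatrix(scores), [f"c{i}" for i in range(10)]
        )
        assert out.thresholds["a1"] == pytest.approx(
            quantile_oracle(range(10), 0.9)
        )
        assert bool(out.calls.loc["a1", "t1"])
        assert not bool(out.calls.loc["a1", "t2"])

    def test_controls_self_called_at_expected_rate(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(40, 200)),
            columns=[f"c{i}" for i in range(200)],
        )
        out = call_positivity(d.ReactivityScoreMatrix(scores), list(scores.columns))
        # strictly above the 90th percentile of themselves: ~10% per antigen
        rate = out.calls.mean(axis=1)
        assert abs(rate.mean() - 0.1) < 0.01

    def test_too_few_controls_skipped(self, rng):
        scores = pd.DataFrame(rng.normal(size=(2, 6)), columns=list("abcdef"))
        scores.iloc[1, :3] = np.nan
        out = call_positivity(
            d.ReactivityScoreMatrix(scores), list("abcdef"), min_controls=5
        )
        assert out.skipped_antigens == [1]


class TestClinicalAssays:
    @pytest.mark.parametrize(
        "signal,expected", [(10.0, 0.0), (110.0, 1.0), (60.0, 0.5)]
    )
    def test_tpo_index_endpoints(self, signal, expected):
        assert tpo_index(signal, 10.0, 110.0) == pytest.approx(expected)

    def test_tpo_assay_failure(self):
        with pytest.raises(ValueError):
            tpo_index(5.0, 10.0, 10.0)

    def test_tpo_threshold_is_percentile(self, rng):
        v = rng.normal(size=100)
        assert tpo_threshold(v) == pytest.approx(np.percentile(v, 95))

    def test_ana_ratio_rule_boundary(self):
        assert ana_call(2.1, 1.0)
        assert not ana_call(2.0999, 1.0)
        assert not ana_call(0.0, 1.0)
        with pytest.raises(ValueError):
            ana_call(1.0, 0.0)


class TestOverrepresentation:
    @staticmethod
    def _calls(df):
        return d.PositivityCalls(
            calls=df, thresholds=pd.Series(dtype=float), reference_group="D21"
        )

    def test_low_detection_antigen_excluded(self, rng):
        n = 100
        samples = [f"s{i}" for i in range(n)]
        groups = pd.Series(["T21"] * 60 + ["D21"] * 40, index=samples)
        calls = pd.DataFrame(
            {
                s: [rng.random() < 0.5, i < 17]
                for i, s in enumerate(samples)
            },
            index=["common", "rare"],
        )
        out = overrepresentation_screen(self._calls(calls), groups, min_detected=18)
        assert list(out["antigen"]) == ["common"]

    def test_equal_rates_give_null_or(self):
        samples = [f"s{i}" for i in range(40)]
        groups = pd.Series(["T21"] * 20 + ["D21"] * 20, index=samples)
        calls = pd.DataFrame(
            {s: [i % 2 == 0] for i, s in enumerate(samples)}, index=["a"]
        )
        out = overrepresentation_screen(self._calls(calls), groups, min_detected=5)
        assert out.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert out.loc[0, "q_value"] >= out.loc[0, "p_value"] - 1e-12

    def test_enriched_antigen_detected_end_to_end(self):
        part = d.cohort.simulate_participants(
            d.CohortSpec(n_t21=300, n_d21=150, seed=21)
        )
        eff = d.EffectSpec(enriched_antigens={"AG001": 9.0})
        arr = d.cohort.simulate_autoantigen_mfi(part, eff, n_antigens=50, seed=22)
        scores = mad_transform(arr)
        calls = call_positivity(scores, part.index[part["karyotype"] == "D21"])
        out = overrepresentation_screen(calls, part["karyotype"])
        top = out.iloc[0]
        assert top["antigen"] == "AG001"
        assert top["q_value"] < 0.1
        assert top["odds_ratio"] > 1


class TestBurdenAndPhenotypes:
    def test_burden_conservation_and_partition(self, rng):
        calls = pd.DataFrame(
            rng.random((20, 30)) < 0.2,
            index=[f"a{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(30)],
        )
        pc = d.PositivityCalls(
            calls=calls, thresholds=pd.Series(dtype=float), reference_group="D21"
        )
        counts, bands = positivity_burden(pc)
        assert counts.sum() == calls.values.sum()
        assert bands["proportion"].sum() == pytest.approx(1.0)

    def test_phenotype_with_too_few_cases_skipped(self, rng):
        calls = pd.DataFrame(
            rng.random((5, 30)) < 0.3, columns=[f"s{i}" for i in range(30)]
        )
        pc = d.PositivityCalls(
            calls=calls, thresholds=pd.Series(dtype=float), reference_group="D21"
        )
        pheno = pd.DataFrame(
            {
                "rare": [True] * 4 + [False] * 26,
                "common": [True] * 10 + [False] * 20,
            },
            index=calls.columns,
        )
        out = phenotype_association_screen(pc, pheno, min_cases=5)
        assert set(out["phenotype"]) == {"common"}
        assert out.attrs["bh_family"] == "within phenotype, across antigens"

    def test_perfectly_associated_antigen(self):
        samples = [f"s{i}" for i in range(100)]
        calls = pd.DataFrame(
            {s: [i < 10] for i, s in enumerate(samples)}, index=["a"]
        )
        pc = d.PositivityCalls(
            calls=calls, thresholds=pd.Series(dtype=float), reference_group="D21"
        )
        pheno = pd.DataFrame({"cond": [i < 50 for i in range(100)]}, index=samples)
        out = phenotype_association_screen(pc, pheno)
        from oracles import fisher_two_sided_oracle

        assert out.loc[0, "p_value"] == pytest.approx(
            fisher_two_sided_oracle(10, 40, 0, 50), rel=1e-9
        )
        # zero cell -> Haldane-corrected OR
        assert out.loc[0, "odds_ratio"] == pytest.approx(
            (10.5 * 50.5) / (40.5 * 0.5)
        )


def test_positivity_invariant_under_sample_rescaling(rng):
    vals = rng.lognormal(3, 1, (40, 30))
    scale = rng.uniform(0.5, 2.0, size=30)
    shift = rng.uniform(0, 5, size=30)
    a = mad_transform(_matrix(vals))
    b = mad_transform(_matrix(vals * scale + shift))
    controls = list(a.mad_scores.columns[:10])
    ca = call_positivity(a, controls)
    cb = call_positivity(b, controls)
    pd.testing.assert_frame_equal(ca.calls, cb.calls)
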