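"""Rule-based DTA/BSA/artifact classification."""

import dataclasses

import numpy as np
import pytest

from ventwave import (
    BreathMetadata,
    CohortSpec,
    PatientModel,
    RuleParameters,
    build_classification_matrix,
    classify_bsa,
    classify_dta,
    simulate_cohort,
)


def meta(**kw):
    defaults = dict(
        tvi=450.0, tve=430.0, i_time=1.0, e_time=1.2, ratio_tve_tvi=430 / 450,
        pip=20.0, peep=5.0, peak_insp_flow=0.5, peak_exp_flow=0.9, end_exp_flow=-0.02,
    )
    defaults.update(kw)
    if "ratio_tve_tvi" not in kw and {"tve", "tvi"} & set(kw):
        defaults["ratio_tve_tvi"] = defaults["tve"] / defaults["tvi"] if defaults["tvi"] else 0.0
    return BreathMetadata(**defaults)


class TestClassifyDta:
    def test_air_trapping_with_short_etime_fires(self):
        prev = meta(tve=20.0, e_time=0.10)
        assert classify_dta(prev, meta()) == (True, True)

    def test_physiologic_breath_does_not_fire(self):
        prev = meta(tve=400.0, tvi=500.0, e_time=1.2)
        assert classify_dta(prev, meta()) == (False, False)

    def test_no_successor_cannot_be_a_double_trigger(self):
        prev = meta(tve=20.0, e_time=0.10)
        assert classify_dta(prev, None) == (False, False)

    def test_zero_tvi_is_excluded(self):
        prev = meta(tvi=0.0, tve=0.0, ratio_tve_tvi=0.0, e_time=0.1, ratio_undefined=True)
        assert classify_dta(prev, meta()) == (False, False)

    @pytest.mark.parametrize(
        "field, value",
        [("ratio", 0.30), ("e_time", 0.40), ("tve", 200.0)],
    )
    def test_each_clause_is_necessary(self, field, value):
        kw = dict(tve=20.0, e_time=0.10)
        if field == "ratio":
            prev = meta(**kw)
            prev = dataclasses.replace(prev, ratio_tve_tvi=value)
        elif field == "e_time":
            prev = meta(tve=20.0, e_time=value)
        else:
            prev = meta(tve=value, e_time=0.10)
        assert classify_dta(prev, meta())[0] is False


class TestClassifyBsa:
    def test_low_ratio_physiologic_etime_fires(self):
        assert classify_bsa(meta(tvi=450.0, tve=360.0, e_time=1.2)) is True

    def test_ratio_at_or_above_ninety_percent_is_too_subtle(self):
        assert classify_bsa(meta(tvi=450.0, tve=430.0, e_time=1.2)) is False

    def test_dta_regime_etime_is_excluded(self):
        assert classify_bsa(meta(tvi=450.0, tve=360.0, e_time=0.2)) is False

    def test_small_breaths_are_ineligible(self):
        assert classify_bsa(meta(tvi=80.0, tve=40.0, e_time=1.2)) is False


class TestRuleParameters:
    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            RuleParameters(bsa_ratio_max=-1.0)

    def test_dta_ratio_must_stay_below_bsa_ratio(self):
        with pytest.raises(ValueError):
            RuleParameters(dta_ratio_max=0.95)


class TestBuildClassificationMatrix:
    def test_artifact_free_cohort_has_no_flags(self, clean_cohort):
        m = build_classification_matrix(clean_cohort.record)
        df = m.df
        assert len(m) == len(clean_cohort.truth)
        for col in ("dta", "dta_partner", "bsa", "suction", "cough", "disconnect"):
            assert df[col].sum() == 0, col

    def test_injected_dta_pairs_recovered_exactly(self):
        cohort = simulate_cohort(CohortSpec(n_breaths=100, dta_pct=0.05, seed=21))
        m = build_classification_matrix(cohort.record)
        truth_first = (
            (cohort.truth.label == "dta")
            & (cohort.truth.label.shift(-1) == "dta")
            & (cohort.truth.label.shift(1) != "dta")
        )
        assert m.df["dta"].sum() == 5
        assert m.df["dta_partner"].sum() == 5
        assert (m.df["dta"].to_numpy() == truth_first.to_numpy()).all()

    def test_dta_and_bsa_are_mutually_exclusive(self, mixed_cohort):
        df = build_classification_matrix(mixed_cohort.record).df
        assert not (df["dta"] & df["bsa"]).any()
        assert not (df["dta_partner"] & df["bsa"]).any()

    def test_corrected_flags_initialised_to_raw(self, mixed_cohort):
        df = build_classification_matrix(mixed_cohort.record).df
        assert (df["corrected_dta"] == df["dta"]).all()
        assert (df["corrected_bsa"] == df["bsa"]).all()
        assert (df["tvv_class"] == -1).all()

    def test_deterministic(self, mixed_cohort):
        m1 = build_classification_matrix(mixed_cohort.record)
        m2 = build_classification_matrix(mixed_cohort.record)
        assert m1.equals(m2)

    def test_raising_bsa_ratio_max_never_loses_detections(self, mixed_cohort):
        lo = build_classification_matrix(
            mixed_cohort.record, RuleParameters(bsa_ratio_max=0.7)
        )
        hi = build_classification_matrix(
            mixed_cohort.record, RuleParameters(bsa_ratio_max=0.9)
        )
        assert hi.df["bsa"].sum() >= lo.df["bsa"].sum()
        assert (hi.df["bsa"] | ~lo.df["bsa"]).all()  # lo positives stay positive

    def test_empty_record_yields_empty_matrix(self):
        from conftest import make_record

        m = build_classification_matrix(make_record(np.zeros(100)))
        assert len(m) == 0


class TestDetectArtifacts:
    def test_disconnect_window_flags_overlapping_breaths(self):
        cohort = simulate_cohort(
            CohortSpec(n_breaths=30, artifact_pct=0.1, seed=33,
                       patient=PatientModel(noise_sd=0.0))
        )
        df = build_classification_matrix(cohort.record).df
        truth = cohort.truth
        disc = truth.label == "disconnect"
        if disc.any():
            assert df.loc[disc.to_numpy(), "disconnect"].all()

    def test_cough_spike_detected_relative_to_cohort(self, mixed_cohort):
        df = build_classification_matrix(mixed_cohort.record).df
        truth = mixed_cohort.truth
        cough = (truth.label == "cough").to_numpy()
        if cough.any():
            assert df.loc[cough, "cough"].all()
        # normal breaths never reach twice the cohort median expiratory peak
        normal = (truth.label == "none").to_numpy()
        assert not df.loc[normal, "cough"].any()

    def test_suction_needs_a_run(self, mixed_cohort):
        df = build_classification_matrix(mixed_cohort.record).df
        truth = mixed_cohort.truth
        suction = (truth.label == "suction").to_numpy()
        if suction.any():
            assert df.loc[suction, "suction"].all()
        assert not df.loc[(truth.label == "none").to_numpy(), "suction"].any()

    def test_isolated_short_breath_is_not_suction(self):
        # a single low-amplitude short cycle cannot form a run of three
        from ventwave.metadata import BreathMetadata
        from ventwave.rules import detect_artifacts
        from ventwave.segmentation import Breath

        from conftest import make_record

        flow = np.concatenate([np.zeros(10), np.full(10, 0.4), [0.0],
                               np.full(10, -0.1), np.zeros(10)])
        rec = make_record(flow)
        breaths = [Breath(10, 31, 20, 0)]
        metas = [
            BreathMetadata(tvi=80, tve=20, i_time=0.2, e_time=0.22,
                           ratio_tve_tvi=0.25, pip=7.0, peep=5.0,
                           peak_insp_flow=0.4, peak_exp_flow=0.1, end_exp_flow=-0.1)
        ]
        flags = detect_artifacts(breaths, metas, rec)
        assert not flags["suction"].any()
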