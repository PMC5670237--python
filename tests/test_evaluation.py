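"""Patient-weighted performance estimation, correction deltas, TOST, TVV shift."""

import numpy as np
import pandas as pd
import pytest

from ventwave.evaluation import (
    compare_correction_effect,
    confusion_by_patient,
    performance_metrics,
    tost_equivalence,
    tvv_shift_test,
)
from ventwave.rules import ClassificationMatrix
from ventwave.vwd_io import GoldStandardAnnotation

from test_postprocess import make_matrix


def annotations(labels, patient="p1"):
    return [
        GoldStandardAnnotation(i, frozenset({lab}), patient)
        for i, lab in enumerate(labels)
    ]


def synthetic_pair(tp, fp, tn, fn, patient="p1", event="bsa"):
    """A matrix/gold pair with an exact confusion table for `event`."""
    rows, labels = [], []
    for _ in range(tp):
        rows.append({event: True}); labels.append(event)
    for _ in range(fp):
        rows.append({event: True}); labels.append("none")
    for _ in range(tn):
        rows.append({}); labels.append("none")
    for _ in range(fn):
        rows.append({}); labels.append(event)
    return make_matrix(rows), annotations(labels, patient)


class TestPerformanceMetrics:
    def test_single_patient_reduces_to_raw_proportion(self):
        m, g = synthetic_pair(tp=94, fp=0, tn=0, fn=6)
        rep = performance_metrics(m, g, "bsa")["sensitivity"]
        assert rep.estimate == pytest.approx(0.94, abs=1e-9)
        assert rep.ci_low <= rep.estimate <= rep.ci_high

    def test_identical_proportions_are_weight_invariant(self):
        m1, g1 = synthetic_pair(tp=9, fp=0, tn=5, fn=1, patient="a")
        m2, g2 = synthetic_pair(tp=90, fp=0, tn=50, fn=10, patient="b")
        rep = performance_metrics([m1, m2], [g1, g2], "bsa")["sensitivity"]
        assert rep.estimate == pytest.approx(0.9, abs=1e-8)

    def test_heterogeneous_cohort_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(17)
        mats, golds, props, weights = [], [], [], []
        for p in range(10):
            pos = int(rng.integers(5, 40))
            tp = int(rng.integers(1, pos + 1))
            m, g = synthetic_pair(tp=tp, fp=0, tn=20, fn=pos - tp, patient=f"p{p}")
            mats.append(m); golds.append(g)
            props.append(tp / pos); weights.append(pos)
        rep = performance_metrics(mats, golds, "bsa")["sensitivity"]
        oracle = np.average(props, weights=weights)
        assert rep.estimate == pytest.approx(oracle, abs=1e-6)

    def test_dta_prediction_counts_both_components(self):
        m = make_matrix([
            {"dta": True, "ratio_tve_tvi": 0.05},
            {"dta_partner": True},
            {},
        ])
        g = annotations(["dta", "dta", "none"])
        conf = confusion_by_patient(m, g, "dta")
        assert conf.loc[0, "tp"] == 2
        assert conf.loc[0, "fn"] == 0

    def test_zero_eligible_breaths_is_undefined(self):
        m, g = synthetic_pair(tp=0, fp=0, tn=10, fn=0)
        rep = performance_metrics(m, g, "bsa")["sensitivity"]
        assert rep.undefined

    def test_mismatched_lengths_rejected(self):
        m, g = synthetic_pair(tp=1, fp=0, tn=3, fn=0)
        with pytest.raises(ValueError, match="mismatch|breaths"):
            confusion_by_patient(m, g[:-1], "bsa")


class TestCorrectionEffect:
    def test_identity_correction_gives_zero_delta_p_one(self):
        m, g = synthetic_pair(tp=10, fp=2, tn=30, fn=1)
        # corrected flags equal raw by construction in make_matrix
        out = compare_correction_effect([m, m], [g, _repatient(g, "p2")], "bsa")
        assert out["specificity"].delta == 0.0
        assert out["specificity"].p_value == pytest.approx(1.0)

    def test_removing_false_positives_moves_only_specificity(self):
        mats, golds = [], []
        for p in ("a", "b", "c"):
            m, g = synthetic_pair(tp=10, fp=4, tn=26, fn=0, patient=p)
            df = m.to_frame()
            # correction clears exactly the false positives
            truth = np.array([lab == "bsa" for lab in ("bsa",) * 10 + ("none",) * 30])
            df["corrected_bsa"] = df["bsa"] & truth
            mats.append(ClassificationMatrix(df)); golds.append(g)
        out = compare_correction_effect(mats, golds, "bsa")
        assert out["specificity"].delta > 0
        assert out["sensitivity"].delta == pytest.approx(0.0)

    def test_three_patient_equal_weight_mean(self):
        mats, golds = [], []
        for p, extra in zip("abc", (2, 4, 6)):
            # 100 gold negatives each; correction repairs `extra` false positives
            m, g = synthetic_pair(tp=5, fp=10, tn=90, fn=0, patient=p)
            df = m.to_frame()
            flips = np.flatnonzero((df["bsa"] & ~np.array(
                [lab == "bsa" for lab in ("bsa",) * 5 + ("none",) * 100])).to_numpy())
            df.loc[flips[:extra], "corrected_bsa"] = False
            mats.append(ClassificationMatrix(df)); golds.append(g)
        out = compare_correction_effect(mats, golds, "bsa")
        assert out["specificity"].delta == pytest.approx(0.04, abs=1e-9)

    def test_single_patient_has_undefined_ci(self):
        m, g = synthetic_pair(tp=10, fp=2, tn=30, fn=1)
        df = m.to_frame()
        df.loc[10, "corrected_bsa"] = False  # repair one false positive
        out = compare_correction_effect(ClassificationMatrix(df), g, "bsa")
        assert not out["specificity"].ci_defined


def _repatient(gold, patient):
    return [GoldStandardAnnotation(a.breath_index, a.labels, patient) for a in gold]


class TestTost:
    def test_tiny_spread_around_zero_is_equivalent(self):
        r = tost_equivalence([0.1, -0.1, 0.05, -0.02], [10, 10, 10, 10], margin=10)
        assert r.equivalent
        assert r.p_value < 0.05

    def test_mean_outside_margin_is_not_equivalent(self):
        r = tost_equivalence([15.0, 14.0, 16.0, 15.5], [10, 10, 10, 10], margin=10)
        assert not r.equivalent

    def test_margin_must_be_positive(self):
        with pytest.raises(ValueError):
            tost_equivalence([1.0, 2.0], [1, 1], margin=0.0)

    def test_small_true_bias_with_large_n_is_equivalent(self):
        rng = np.random.default_rng(7)
        groups = rng.normal(3.0, 1.0, size=8)   # true +3% bias, tight groups
        weights = np.full(8, 40)
        r = tost_equivalence(groups, weights, margin=10)
        assert r.equivalent
        assert -10 < r.ci_low and r.ci_high < 10

    def test_decision_matches_ninety_percent_ci_containment(self):
        """TOST at alpha=0.05 is the 90% CI inside (-m, m) rule, checked over
        2000 random weighted samples against a closed-form WLS oracle."""
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(42)
        agree = 0
        for _ in range(2000):
            k = int(rng.integers(3, 12))
            vals = rng.normal(rng.uniform(-15, 15), rng.uniform(0.5, 8.0), size=k)
            w = rng.integers(1, 50, size=k).astype(float)
            r = tost_equivalence(vals, w, margin=10)
            # closed-form weighted-least-squares intercept and its SE
            mean = np.sum(w * vals) / np.sum(w)
            s2 = np.sum(w * (vals - mean) ** 2) / (k - 1)
            se = np.sqrt(s2 / np.sum(w))
            tcrit = t_dist.ppf(0.95, k - 1)
            inside = (mean - tcrit * se > -10) and (mean + tcrit * se < 10)
            assert r.mean == pytest.approx(mean, rel=1e-9)
            agree += r.equivalent == inside
        assert agree == 2000

    def test_type_one_error_at_the_margin(self):
        """With the true mean exactly at +margin the equivalence rate stays
        at or below the nominal 5% (within +/-1% over 2000 replicates)."""
        rng = np.random.default_rng(3)
        declared = 0
        n_rep = 2000
        for _ in range(n_rep):
            vals = rng.normal(10.0, 2.0, size=8)
            declared += tost_equivalence(vals, np.full(8, 25.0), margin=10).equivalent
        assert declared / n_rep <= 0.05 + 0.01


class TestTvvShift:
    def test_no_shift(self):
        r = tvv_shift_test([0, 1, 2], [0, 1, 2], ["p"] * 3)
        assert r.mean_shift == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_uniform_two_class_shift(self):
        r = tvv_shift_test([0, 0, 0], [2, 2, 2], ["p"] * 3)
        assert r.mean_shift == pytest.approx(2.0)

    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(5)
        patients, unfused, fused = [], [], []
        for p in range(6):
            n = int(rng.integers(3, 20))
            u = rng.integers(0, 2, size=n)
            f = u + rng.integers(0, 3, size=n)
            patients += [f"p{p}"] * n
            unfused += list(u)
            fused += list(np.clip(f, 0, 3))
        r = tvv_shift_test(unfused, fused, patients)
        df = pd.DataFrame({"p": patients, "d": np.array(fused) - np.array(unfused)})
        per = df.groupby("p")["d"].agg(["mean", "count"])
        oracle = np.average(per["mean"], weights=per["count"])
        assert r.mean_shift == pytest.approx(oracle, abs=1e-9)

    def test_empty_input_is_a_domain_error(self):
        with pytest.raises(ValueError):
            tvv_shift_test([], [], [])
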