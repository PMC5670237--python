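"""Patient-weighted performance statistics for the detection algorithms.

Sensitivity, specificity and accuracy are estimated by intercept-only
logistic regression on per-patient correct-classification proportions, with
the patient-specific gold-standard counts as weights (positives for
sensitivity, negatives for specificity, total breaths for accuracy), so that
patients contribute in proportion to their eligible breaths while the fit
remains robust to between-patient heterogeneity.  With a single patient the
weighted estimate reduces exactly to the raw proportion.

Correction effects and TVV class shifts use intercept-only weighted least
squares on per-patient differences; equivalence of tidal-volume measurement
uses two one-sided t-tests (TOST) built from the same weighted-least-squares
intercept, against a prespecified +/-10% margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import t as t_dist

from .rules import ClassificationMatrix
from .vwd_io import GoldStandardAnnotation

__all__ = [
    "PerformanceReport",
    "DeltaReport",
    "TostResult",
    "ShiftResult",
    "confusion_by_patient",
    "performance_metrics",
    "compare_correction_effect",
    "tost_equivalence",
    "tvv_shift_test",
    "write_evaluation_report",
]

METRICS = ("sensitivity", "specificity", "accuracy")
EVENTS = ("dta", "bsa", "artifact")
_ARTIFACT_LABELS = {"suction", "cough", "disconnect"}


@dataclass(frozen=True)
class PerformanceReport:
    """Weighted estimate of one performance metric with its 95% CI."""

    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    n_patients: int
    n_breaths: int
    undefined: bool = False


@dataclass(frozen=True)
class DeltaReport:
    """Corrected-minus-raw change in one metric (WLS intercept)."""

    metric: str
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    ci_defined: bool = True


@dataclass(frozen=True)
class TostResult:
    """Two one-sided tests of equivalence against a symmetric margin."""

    mean: float
    ci_low: float       # 95% two-sided CI
    ci_high: float
    p_value: float      # larger of the two one-sided p-values
    margin: float
    equivalent: bool


@dataclass(frozen=True)
class ShiftResult:
    """Mean per-breath TVV class shift (fused - unfused)."""

    mean_shift: float
    ci_low: float
    ci_high: float
    p_value: float


def _as_pairs(
    matrix: ClassificationMatrix | Sequence[ClassificationMatrix],
    gold: Sequence[GoldStandardAnnotation] | Sequence[Sequence[GoldStandardAnnotation]],
) -> list[tuple[ClassificationMatrix, list[GoldStandardAnnotation]]]:
    if isinstance(matrix, ClassificationMatrix):
        return [(matrix, list(gold))]  # type: ignore[arg-type]
    return [(m, list(g)) for m, g in zip(matrix, gold, strict=True)]


def _predicted(matrix: ClassificationMatrix, event: str, corrected: bool) -> np.ndarray:
    """Per-breath predicted-positive array for an event class.

    For DTA both components count as predicted positive; when evaluating the
    corrected output a partner counts only if its first component survived
    correction.
    """
    if event == "dta":
        if corrected:
            first = matrix["corrected_dta"]
        else:
            first = matrix["dta"]
        partner = np.zeros(len(matrix), dtype=bool)
        partner[1:] = first[:-1] & matrix["dta_partner"][1:]
        return first | partner
    if event == "bsa":
        return matrix["corrected_bsa"] if corrected else matrix["bsa"]
    if event == "artifact":
        return matrix.artifact_any()
    raise ValueError(f"unknown event {event!r}")


def _truth(gold: list[GoldStandardAnnotation], event: str) -> np.ndarray:
    if event == "artifact":
        return np.array([bool(a.labels & _ARTIFACT_LABELS) for a in gold])
    return np.array([event in a.labels for a in gold])


def confusion_by_patient(
    matrix: ClassificationMatrix | Sequence[ClassificationMatrix],
    gold,
    event: str,
    corrected: bool = False,
) -> pd.DataFrame:
    """Per-patient confusion counts (tp, fp, tn, fn) for one event class.

    The gold annotations must cover every breath of the matching matrix, in
    breath order.
    """
    rows = []
    for m, g in _as_pairs(matrix, gold):
        g = sorted(g, key=lambda a: a.breath_index)
        if len(g) != len(m):
            raise ValueError(
                f"gold standard has {len(g)} breaths but matrix has {len(m)}"
            )
        pred = _predicted(m, event, corrected)
        truth = _truth(g, event)
        patient = g[0].patient_id if g else ""
        rows.append(
            {
                "patient_id": patient,
                "tp": int(np.sum(pred & truth)),
                "fp": int(np.sum(pred & ~truth)),
                "tn": int(np.sum(~pred & ~truth)),
                "fn": int(np.sum(~pred & truth)),
            }
        )
    return pd.DataFrame(rows)


def _weighted_logistic(props: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """Intercept-only binomial GLM on proportions with variance weights.

    Returns (estimate, ci_low, ci_high) on the probability scale; the CI is
    computed on the logit scale from the intercept's standard error and
    transformed back.
    """
    pooled = float(np.sum(props * weights) / np.sum(weights))
    if pooled <= 0.0 or pooled >= 1.0:
        # complete separation: the MLE is the boundary; no finite logit CI
        return pooled, pooled, pooled
    if len(props) == 1 or np.ptp(props) == 0.0:
        # no between-patient spread: degenerate (point) interval
        return pooled, pooled, pooled
    model = sm.GLM(props, np.ones((len(props), 1)),
                   family=sm.families.Binomial(), var_weights=weights)
    res = model.fit()
    lo, hi = res.conf_int()[0]
    return float(expit(res.params[0])), float(expit(lo)), float(expit(hi))


def _metric_components(metric: str, c: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(numerator of correct, eligible count) per patient for a metric."""
    if metric == "sensitivity":
        correct, total = c["tp"], c["tp"] + c["fn"]
    elif metric == "specificity":
        correct, total = c["tn"], c["tn"] + c["fp"]
    elif metric == "accuracy":
        correct, total = c["tp"] + c["tn"], c["tp"] + c["fp"] + c["tn"] + c["fn"]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return correct.to_numpy(float), total.to_numpy(float)


def performance_metrics(
    matrix,
    gold,
    event: str,
    corrected: bool = False,
) -> dict[str, PerformanceReport]:
    """Patient-weighted sensitivity, specificity and accuracy for one event.

    Accepts one matrix with its annotations, or parallel sequences of
    per-patient matrices and annotation lists.
    """
    conf = confusion_by_patient(matrix, gold, event, corrected)
    n_patients = len(conf)
    reports: dict[str, PerformanceReport] = {}
    for metric in METRICS:
        correct, total = _metric_components(metric, conf)
        mask = total > 0
        n_breaths = int(np.sum(total))
        if not mask.any():
            reports[metric] = PerformanceReport(
                metric, float("nan"), float("nan"), float("nan"),
                n_patients, 0, undefined=True,
            )
            continue
        props = correct[mask] / total[mask]
        est, lo, hi = _weighted_logistic(props, total[mask])
        reports[metric] = PerformanceReport(
            metric, est, lo, hi, n_patients, n_breaths
        )
    return reports


def _wls_intercept(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, int]:
    """(intercept, standard error, residual df) of intercept-only WLS."""
    res = sm.WLS(values, np.ones((len(values), 1)), weights=weights).fit()
    return float(res.params[0]), float(res.bse[0]), int(res.df_resid)


def compare_correction_effect(
    matrix,
    gold,
    event: str,
) -> dict[str, DeltaReport]:
    """Per-metric change (corrected - raw) with CI and p-value.

    Per-patient metric differences are fitted with intercept-only weighted
    least squares using the gold-standard count weights; the intercept is the
    mean change, tested two-sided against zero.
    """
    raw = confusion_by_patient(matrix, gold, event, corrected=False)
    cor = confusion_by_patient(matrix, gold, event, corrected=True)
    reports: dict[str, DeltaReport] = {}
    for metric in METRICS:
        r_correct, r_total = _metric_components(metric, raw)
        c_correct, c_total = _metric_components(metric, cor)
        mask = r_total > 0
        deltas = c_correct[mask] / c_total[mask] - r_correct[mask] / r_total[mask]
        weights = r_total[mask]
        if len(deltas) == 0:
            reports[metric] = DeltaReport(metric, float("nan"), float("nan"),
                                          float("nan"), float("nan"), ci_defined=False)
            continue
        if len(deltas) == 1:
            reports[metric] = DeltaReport(metric, float(deltas[0]), float("nan"),
                                          float("nan"), float("nan"), ci_defined=False)
            continue
        if np.allclose(deltas, 0.0):
            reports[metric] = DeltaReport(metric, 0.0, 0.0, 0.0, 1.0)
            continue
        mean, se, df = _wls_intercept(deltas, weights)
        if se == 0.0:
            reports[metric] = DeltaReport(metric, mean, mean, mean, 0.0)
            continue
        tcrit = t_dist.ppf(0.975, df)
        p = 2.0 * t_dist.sf(abs(mean / se), df)
        reports[metric] = DeltaReport(metric, mean, mean - tcrit * se,
                                      mean + tcrit * se, float(p))
    return reports


def tost_equivalence(
    pct_differences: Iterable[float],
    weights: Iterable[float],
    margin: float = 10.0,
) -> TostResult:
    """TOST equivalence of a weighted mean percent difference to zero.

    The mean and its standard error come from intercept-only weighted least
    squares over the per-group percent differences; the two one-sided t-tests
    are taken against ``+/-margin`` at alpha = 0.05, so equivalence is
    declared exactly when the 90% CI lies inside the margin.
    """
    if margin <= 0:
        raise ValueError("equivalence margin must be positive")
    values = np.asarray(list(pct_differences), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if len(values) < 2:
        raise ValueError("TOST needs at least two groups of differences")
    mean, se, df = _wls_intercept(values, w)
    if se == 0.0:
        inside = abs(mean) < margin
        return TostResult(mean, mean, mean, 0.0 if inside else 1.0, margin, inside)
    t_lower = (mean + margin) / se   # H0: mean <= -margin
    t_upper = (mean - margin) / se   # H0: mean >= +margin
    p_lower = float(t_dist.sf(t_lower, df))
    p_upper = float(t_dist.cdf(t_upper, df))
    p = max(p_lower, p_upper)
    tcrit = t_dist.ppf(0.975, df)
    return TostResult(
        mean=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        p_value=p,
        margin=margin,
        equivalent=p < 0.05,
    )


def tvv_shift_test(
    unfused_classes: Iterable[int],
    fused_classes: Iterable[int],
    patient_ids: Iterable[str],
) -> ShiftResult:
    """Mean per-breath TVV class shift (fused - unfused), patient-weighted.

    Integer per-breath class differences are averaged per patient and fitted
    with intercept-only weighted least squares, weighting by the number of
    breaths per patient.
    """
    unfused = np.asarray(list(unfused_classes), dtype=int)
    fused = np.asarray(list(fused_classes), dtype=int)
    patients = np.asarray(list(patient_ids))
    if len(unfused) == 0:
        raise ValueError("empty input")
    if not (len(unfused) == len(fused) == len(patients)):
        raise ValueError("class lists and patient ids must be aligned")
    diff = fused - unfused
    df = pd.DataFrame({"patient": patients, "diff": diff})
    per_patient = df.groupby("patient")["diff"].agg(["mean", "count"])
    means = per_patient["mean"].to_numpy(float)
    counts = per_patient["count"].to_numpy(float)
    if len(means) == 1 or np.allclose(means, means[0]):
        shift = float(np.sum(means * counts) / np.sum(counts))
        p = 1.0 if shift == 0.0 else 0.0
        return ShiftResult(shift, shift, shift, p)
    mean, se, dof = _wls_intercept(means, counts)
    tcrit = t_dist.ppf(0.975, dof)
    p = 2.0 * t_dist.sf(abs(mean / se), dof)
    return ShiftResult(mean, mean - tcrit * se, mean + tcrit * se, float(p))


def write_evaluation_report(reports: list[dict], path) -> None:
    """Write an evaluation report CSV.

    Each entry: metric, event, corrected flag, estimate, ci_low, ci_high and
    p_value (NaN where not applicable).
    """
    pd.DataFrame(
        reports,
        columns=["event", "metric", "corrected", "estimate", "ci_low", "ci_high", "p_value"],
    ).to_csv(path, index=False)
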