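"""Artifact correction, tidal-volume fusion, PBW normalisation and TVV grading.

Artifact correction implements the heuristic "any detected PVA that is also
recognised as a clinical artifact is not PVA": a DTA is removed when either
component breath carries an artifact flag, a BSA when the breath itself does.

TV-fusion replaces a double-trigger pair's volumes with the effective
distending volume TVi1 + TVi2 - TVe1 (the intervening exhalation, if any, is
subtracted).  Chains of three or more consecutive DTA-flagged breaths fold
left-to-right into a single fused volume.

Tidal-volume violations (TVV) are graded per breath in ml per kg of
predicted body weight (PBW): class 0 (on target, <= ``target``), 1 (mild),
2 (moderate) or 3 (severe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rules import ClassificationMatrix

__all__ = [
    "TVVGradeScheme",
    "FusedBreath",
    "apply_artifact_correction",
    "fuse_tidal_volumes",
    "predicted_body_weight",
    "grade_tvv",
    "grade_matrix",
    "fused_breath_report",
]


@dataclass(frozen=True)
class TVVGradeScheme:
    """TVV severity bands in ml/kg PBW, and the normalisation subject.

    Defaults: on-target <= 6.5 ml/kg, mild <= 8.5, moderate <= 10.5, severe
    above; normalised to the predicted body weight of a female of average
    U.S. height (161.5 cm).
    """

    target: float = 6.5
    mild_upper: float = 8.5
    moderate_upper: float = 10.5
    pbw_sex: str = "female"
    pbw_height: float = 161.5

    def __post_init__(self) -> None:
        if not (self.target < self.mild_upper < self.moderate_upper):
            raise ValueError("require target < mild_upper < moderate_upper")

    @property
    def pbw(self) -> float:
        return predicted_body_weight(self.pbw_sex, self.pbw_height)


@dataclass(frozen=True)
class FusedBreath:
    """A fused double-trigger event: component ordinals and effective TVi (ml)."""

    first_ordinal: int
    second_ordinal: int
    fused_tvi: float


def apply_artifact_correction(matrix: ClassificationMatrix) -> ClassificationMatrix:
    """Reclassify artifact-coincident PVA as "not PVA".

    ``corrected_dta`` is cleared when the first component or its partner
    carries any artifact flag; ``corrected_bsa`` when the breath itself does.
    Raw and artifact flags are untouched, so correction never increases event
    counts and is the identity on artifact-free matrices.
    """
    if len(matrix) == 0:
        return matrix.replace_columns()
    artifact = matrix.artifact_any()
    dta = matrix["dta"]
    partner_artifact = np.zeros(len(matrix), dtype=bool)
    partner_artifact[:-1] = artifact[1:]  # partner is the next breath
    corrected_dta = dta & ~artifact & ~partner_artifact
    corrected_bsa = matrix["bsa"] & ~artifact
    return matrix.replace_columns(corrected_dta=corrected_dta, corrected_bsa=corrected_bsa)


def fuse_tidal_volumes(matrix: ClassificationMatrix) -> list[FusedBreath]:
    """Fuse corrected DTA pairs (and chains) into effective distending volumes.

    A run of k >= 1 consecutive breaths with ``corrected_dta`` set, followed
    by the terminal partner, folds into one fused breath with
    ``sum(TVi of all k+1 components) - sum(TVe of the k intervening
    exhalations)``, floored at zero.  A flagged breath with no successor is
    skipped with a warning.
    """
    n = len(matrix)
    if n == 0:
        return []
    dta = matrix["corrected_dta"]
    tvi = matrix["tvi"]
    tve = matrix["tve"]
    ordinals = matrix["breath_ordinal"]

    fused: list[FusedBreath] = []
    i = 0
    while i < n:
        if not dta[i]:
            i += 1
            continue
        j = i
        while j < n and dta[j]:
            j += 1
        if j >= n:
            warnings.warn(
                f"DTA at breath {int(ordinals[i])} has no partner at end of record; skipped",
                stacklevel=2,
            )
            break
        # components i..j inclusive; intervening exhalations i..j-1
        volume = float(np.sum(tvi[i:j + 1]) - np.sum(tve[i:j]))
        fused.append(
            FusedBreath(
                first_ordinal=int(ordinals[i]),
                second_ordinal=int(ordinals[j]),
                fused_tvi=max(volume, 0.0),
            )
        )
        i = j + 1
    return fused


def predicted_body_weight(sex: str, height_cm: float) -> float:
    """Predicted body weight (kg) from sex and height.

    Uses the standard lung-protective-ventilation reference equations:
    female 45.5 + 0.905*(height - 152.4), male 50.0 + 0.905*(height - 152.4),
    height in cm within [120, 220].
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not (120.0 <= height_cm <= 220.0):
        raise ValueError(f"height {height_cm} cm outside supported range [120, 220]")
    base = 45.5 if sex == "female" else 50.0
    return base + 0.905 * (height_cm - 152.4)


def grade_tvv(tvi: float, scheme: TVVGradeScheme | None = None) -> int:
    """Grade a tidal volume (ml) into TVV class 0 (on target) .. 3 (severe)."""
    scheme = scheme or TVVGradeScheme()
    if tvi < 0:
        raise ValueError("tidal volume must be non-negative")
    v = tvi / scheme.pbw
    if v <= scheme.target:
        return 0
    if v <= scheme.mild_upper:
        return 1
    if v <= scheme.moderate_upper:
        return 2
    return 3


def grade_matrix(
    matrix: ClassificationMatrix, scheme: TVVGradeScheme | None = None
) -> ClassificationMatrix:
    """Set ``tvv_class`` for every breath from its (unfused) TVi."""
    scheme = scheme or TVVGradeScheme()
    classes = np.array([grade_tvv(v, scheme) for v in matrix["tvi"]], dtype=int)
    return matrix.replace_columns(tvv_class=classes)


def fused_breath_report(
    matrix: ClassificationMatrix, scheme: TVVGradeScheme | None = None
) -> pd.DataFrame:
    """Per-fused-breath report: component ordinals, fused TVi and TVV classes.

    ``tvv_class_unfused`` is the grade of the first component's own TVi;
    ``tvv_class_fused`` grades the effective distending volume.
    """
    scheme = scheme or TVVGradeScheme()
    fused = fuse_tidal_volumes(matrix)
    tvi = matrix["tvi"]
    ordinals = list(matrix["breath_ordinal"])
    rows = []
    for fb in fused:
        first_tvi = float(tvi[ordinals.index(fb.first_ordinal)])
        rows.append(
            {
                "first_ordinal": fb.first_ordinal,
                "second_ordinal": fb.second_ordinal,
                "fused_tvi_ml": fb.fused_tvi,
                "tvv_class_unfused": grade_tvv(first_tvi, scheme),
                "tvv_class_fused": grade_tvv(fb.fused_tvi, scheme),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["first_ordinal", "second_ordinal", "fused_tvi_ml",
                 "tvv_class_unfused", "tvv_class_fused"],
    )
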