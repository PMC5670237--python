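"""Rule-based per-breath classification of off-target ventilation.

Two patient-ventilator asynchrony (PVA) subtypes are detected from breath
metadata:

* **Double-trigger asynchrony (DTA)** — a second machine breath fires with
  essentially no intervening exhalation: low TVe:TVi (air trapping), a
  non-physiologic E-time (<= ~0.3 s) and a small exhaled volume.  The flag is
  carried on the first component breath; the immediately following breath is
  marked ``dta_partner``.
* **Breath-stacking asynchrony (BSA)** — incomplete exhalation (TVe:TVi <
  90%) with a physiologic (> 0.3 s) expiratory time.

Three clinical artifact classes that morphologically mimic PVA are also
flagged: ventilator disconnect (sustained loss of circuit pressure), a subset
of coughs (single high-magnitude expiratory flow spikes), and in-line
suctioning (runs of rapid low-amplitude auto-triggered cycles).

The DTA E-time ceiling and the BSA E-time floor share one threshold
(``dta_etime_max``), so the two rules partition the E-time axis and a breath
can never satisfy both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metadata import BreathMetadata, compute_breath_metadata
from .segmentation import Breath, SegmentationParams, segment_breaths
from .vwd_io import WaveformRecord

__all__ = [
    "RuleParameters",
    "ClassificationMatrix",
    "classify_dta",
    "classify_bsa",
    "detect_artifacts",
    "build_classification_matrix",
]


@dataclass(frozen=True)
class RuleParameters:
    """Thresholds of the detection rules; every field is config-exposed.

    Attributes
    ----------
    bsa_ratio_max:
        BSA fires when TVe:TVi is below this (dimensionless, default 0.90).
    dta_etime_max:
        Maximum (non-physiologic) E-time of a DTA first component, seconds;
        also the E-time floor for BSA.
    dta_ratio_max:
        Maximum TVe:TVi of a DTA first component.
    dta_tve_max:
        Maximum exhaled volume (ml) of a DTA first component.
    disconnect_pressure_max:
        Pressure ceiling (cmH2O) for a disconnect window (loss of PEEP).
    disconnect_min_duration:
        Minimum duration (s) of a sub-threshold pressure window.
    cough_peak_exp_flow_min:
        Absolute expiratory-spike floor for cough (L/s).
    cough_peak_ratio_min:
        Cough spike must also exceed this multiple of the cohort median
        peak expiratory flow.
    suction_min_run:
        Minimum number of consecutive qualifying breaths in a suction run.
    suction_amp_max:
        Maximum pressure amplitude (PIP - PEEP, cmH2O) of a suction cycle.
    bsa_min_tvi:
        Minimum TVi (ml) for a breath to be eligible for BSA.
    """

    bsa_ratio_max: float = 0.90
    dta_etime_max: float = 0.30
    dta_ratio_max: float = 0.25
    dta_tve_max: float = 150.0
    disconnect_pressure_max: float = 2.0
    disconnect_min_duration: float = 1.0
    cough_peak_exp_flow_min: float = 1.5
    cough_peak_ratio_min: float = 2.0
    suction_min_run: int = 3
    suction_amp_max: float = 5.0
    bsa_min_tvi: float = 100.0
    suction_max_duration: float = 1.0

    def __post_init__(self) -> None:
        numeric = [
            self.bsa_ratio_max, self.dta_etime_max, self.dta_ratio_max,
            self.dta_tve_max, self.disconnect_pressure_max,
            self.disconnect_min_duration, self.cough_peak_exp_flow_min,
            self.cough_peak_ratio_min, self.suction_min_run,
            self.suction_amp_max, self.bsa_min_tvi, self.suction_max_duration,
        ]
        if any(v <= 0 for v in numeric):
            raise ValueError("all rule thresholds must be positive")
        if not self.dta_ratio_max < self.bsa_ratio_max:
            raise ValueError("require dta_ratio_max < bsa_ratio_max")


class ClassificationMatrix:
    """Per-breath event flags plus metadata, backed by a pandas DataFrame.

    Columns: breath_ordinal, the :class:`~ventwave.metadata.BreathMetadata`
    fields, raw flags (dta, dta_partner, bsa, suction, cough, disconnect),
    corrected flags (corrected_dta, corrected_bsa) and tvv_class (-1 until
    graded by the postprocess module).
    """

    BOOL_COLS = ["dta", "dta_partner", "bsa", "suction", "cough", "disconnect",
                 "corrected_dta", "corrected_bsa"]
    META_COLS = ["tvi", "tve", "i_time", "e_time", "ratio_tve_tvi",
                 "pip", "peep", "peak_insp_flow", "peak_exp_flow", "end_exp_flow"]

    def __init__(self, df: pd.DataFrame):
        self._df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self._df
        required = ["breath_ordinal", *self.META_COLS, *self.BOOL_COLS, "tvv_class"]
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"matrix missing columns {sorted(missing)}")
        if len(df) and (df["dta"] & df["bsa"]).any():
            raise ValueError("a breath cannot be both DTA and BSA")

    def to_frame(self) -> pd.DataFrame:
        """Return a copy of the underlying DataFrame."""
        return self._df.copy()

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __getitem__(self, col: str) -> np.ndarray:
        return self._df[col].to_numpy()

    def artifact_any(self) -> np.ndarray:
        """Boolean array: breath carries any artifact flag."""
        df = self._df
        return (df["suction"] | df["cough"] | df["disconnect"]).to_numpy()

    def replace_columns(self, **cols: np.ndarray) -> "ClassificationMatrix":
        """Return a new matrix with the given columns replaced."""
        df = self._df.copy()
        for name, values in cols.items():
            df[name] = values
        return ClassificationMatrix(df)

    def equals(self, other: "ClassificationMatrix") -> bool:
        return self._df.equals(other._df)

    @classmethod
    def empty(cls) -> "ClassificationMatrix":
        cols = ["breath_ordinal", *cls.META_COLS, *cls.BOOL_COLS, "tvv_class"]
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
        df["breath_ordinal"] = df["breath_ordinal"].astype(int)
        for c in cls.BOOL_COLS:
            df[c] = df[c].astype(bool)
        df["tvv_class"] = df["tvv_class"].astype(int)
        return cls(df)


def classify_dta(
    prev: BreathMetadata,
    curr: BreathMetadata | None,
    params: RuleParameters | None = None,
) -> tuple[bool, bool]:
    """DTA rule on an adjacent breath pair.

    Returns ``(dta on prev, partner on curr)``.  The first component must
    show air trapping (TVe:TVi below ``dta_ratio_max``), a non-physiologic
    E-time and a small exhaled volume, and a successor breath must exist to
    have been double-triggered.
    """
    params = params or RuleParameters()
    if curr is None:
        return False, False
    if prev.tvi <= 0 or prev.ratio_undefined:
        return False, False
    hit = (
        prev.ratio_tve_tvi < params.dta_ratio_max
        and prev.e_time <= params.dta_etime_max
        and prev.tve < params.dta_tve_max
    )
    return hit, hit


def classify_bsa(meta: BreathMetadata, params: RuleParameters | None = None) -> bool:
    """BSA rule: incomplete exhalation with a physiologic expiratory time."""
    params = params or RuleParameters()
    if meta.tvi <= 0 or meta.ratio_undefined:
        return False
    return (
        meta.ratio_tve_tvi < params.bsa_ratio_max
        and meta.e_time > params.dta_etime_max
        and meta.tvi >= params.bsa_min_tvi
    )


def detect_artifacts(
    breaths: list[Breath],
    metas: list[BreathMetadata],
    record: WaveformRecord,
    params: RuleParameters | None = None,
) -> pd.DataFrame:
    """Flag suction, cough and disconnect artifacts.

    * disconnect — any breath overlapping a contiguous window of at least
      ``disconnect_min_duration`` seconds where pressure stays below
      ``disconnect_pressure_max`` (loss of PEEP);
    * cough — a breath whose peak expiratory flow reaches both the absolute
      floor and ``cough_peak_ratio_min`` times the cohort median peak
      expiratory flow;
    * suction — every breath in a run of at least ``suction_min_run``
      consecutive low-amplitude (PIP - PEEP < ``suction_amp_max``),
      sub-physiologic-duration (< ``suction_max_duration`` s) breaths.
    """
    params = params or RuleParameters()
    n = len(breaths)
    suction = np.zeros(n, dtype=bool)
    cough = np.zeros(n, dtype=bool)
    disconnect = np.zeros(n, dtype=bool)

    if n:
        # --- disconnect: runs of sub-threshold pressure ---------------------
        below = record.pressure < params.disconnect_pressure_max
        min_len = int(round(params.disconnect_min_duration * record.sample_rate))
        edges = np.diff(below.astype(np.int8))
        run_starts = list(np.flatnonzero(edges == 1) + 1)
        run_ends = list(np.flatnonzero(edges == -1) + 1)
        if below[0]:
            run_starts.insert(0, 0)
        if below[-1]:
            run_ends.append(len(below))
        windows = [(a, b) for a, b in zip(run_starts, run_ends) if b - a >= min_len]
        for i, br in enumerate(breaths):
            for a, b in windows:
                if br.start_index < b and a < br.end_index:
                    disconnect[i] = True
                    break

        # --- cough: expiratory spike relative to the cohort -----------------
        peaks = np.array([m.peak_exp_flow for m in metas])
        median_peak = float(np.median(peaks))
        cough = (peaks >= params.cough_peak_exp_flow_min) & (
            peaks >= params.cough_peak_ratio_min * median_peak
        )

        # --- suction: runs of rapid low-amplitude cycles --------------------
        amp = np.array([m.pip - m.peep for m in metas])
        dur = np.array([m.i_time + m.e_time for m in metas])
        qualifies = (amp < params.suction_amp_max) & (dur < params.suction_max_duration)
        run_len = 0
        for i in range(n + 1):
            if i < n and qualifies[i]:
                run_len += 1
                continue
            if run_len >= params.suction_min_run:
                suction[i - run_len:i] = True
            run_len = 0

    return pd.DataFrame({"suction": suction, "cough": cough, "disconnect": disconnect})


def build_classification_matrix(
    record: WaveformRecord,
    params: RuleParameters | None = None,
    seg_params: SegmentationParams | None = None,
) -> ClassificationMatrix:
    """Run segmentation → metadata → DTA → BSA → artifacts on one record.

    DTA takes precedence over BSA: breaths flagged as DTA first components or
    partners are not evaluated for BSA.  Corrected flags are initialised
    equal to the raw flags; ``tvv_class`` is left unset (-1).
    """
    params = params or RuleParameters()
    breaths = segment_breaths(record, seg_params)
    if not breaths:
        return ClassificationMatrix.empty()
    metas = [compute_breath_metadata(record, b) for b in breaths]
    n = len(breaths)

    dta = np.zeros(n, dtype=bool)
    partner = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        hit, _ = classify_dta(metas[i], metas[i + 1], params)
        if hit:
            dta[i] = True
            partner[i + 1] = True

    bsa = np.zeros(n, dtype=bool)
    for i in range(n):
        if dta[i] or partner[i]:
            continue
        bsa[i] = classify_bsa(metas[i], params)

    artifacts = detect_artifacts(breaths, metas, record, params)

    df = pd.DataFrame({"breath_ordinal": [b.breath_ordinal for b in breaths]})
    for col in ClassificationMatrix.META_COLS:
        df[col] = [getattr(m, col) for m in metas]
    df["dta"] = dta
    df["dta_partner"] = partner
    df["bsa"] = bsa
    for col in ("suction", "cough", "disconnect"):
        df[col] = artifacts[col].to_numpy()
    df["corrected_dta"] = dta.copy()
    df["corrected_bsa"] = bsa.copy()
    df["tvv_class"] = -1
    return ClassificationMatrix(df)
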