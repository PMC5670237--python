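"""Reading and writing ventilator waveform data (VWD) and its companion files.

The on-disk waveform dialect is a plain CSV with columns
``time_s, pressure_cmH2O, flow`` sampled uniformly (50 Hz by default), with an
optional leading comment line declaring the flow unit, e.g.::

    # ventwave-vwd flow_unit=L/min sample_rate=50
    0.00,5.2,30.1
    0.02,18.7,29.8

Internally flow is always litres per second (L/s) so that volume integration
is dimensionally direct (L/s x s x 1000 = ml).  Gold-standard annotations and
classification matrices are ordinary CSV files, one row per breath.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ALLOWED_LABELS",
    "VWDDialect",
    "WaveformRecord",
    "GoldStandardAnnotation",
    "VWDFormatError",
    "flow_to_lps",
    "flow_from_lps",
    "read_vwd_file",
    "write_vwd_file",
    "read_gold_standard",
    "write_gold_standard",
    "write_classification_matrix",
    "read_classification_matrix",
]

#: Per-breath annotation vocabulary.  ``none`` is exclusive of all others.
ALLOWED_LABELS = frozenset({"dta", "bsa", "suction", "cough", "disconnect", "none"})

#: Absolute tolerance (seconds) on uniform sample spacing.
_SPACING_TOL = 1e-6


class VWDFormatError(ValueError):
    """Raised for malformed waveform, annotation, or matrix files."""


@dataclass(frozen=True)
class VWDDialect:
    """Column order and units of a waveform CSV file.

    Parameters
    ----------
    flow_unit:
        Unit of the flow column on disk, ``"L/s"`` or ``"L/min"``.
    sample_rate:
        Expected sampling rate in Hz.
    columns:
        Column order in the file.
    """

    flow_unit: str = "L/s"
    sample_rate: float = 50.0
    columns: tuple[str, str, str] = ("time_s", "pressure_cmH2O", "flow")

    def __post_init__(self) -> None:
        if self.flow_unit not in ("L/s", "L/min"):
            raise VWDFormatError(f"unsupported flow unit {self.flow_unit!r}")


def flow_to_lps(values: np.ndarray, unit: str) -> np.ndarray:
    """Convert a flow array from ``unit`` to the canonical L/s."""
    if unit == "L/s":
        return np.asarray(values, dtype=float)
    if unit == "L/min":
        return np.asarray(values, dtype=float) / 60.0
    raise VWDFormatError(f"unsupported flow unit {unit!r}")


def flow_from_lps(values: np.ndarray, unit: str) -> np.ndarray:
    """Convert a canonical L/s flow array to ``unit``."""
    if unit == "L/s":
        return np.asarray(values, dtype=float)
    if unit == "L/min":
        return np.asarray(values, dtype=float) * 60.0
    raise VWDFormatError(f"unsupported flow unit {unit!r}")


@dataclass
class WaveformRecord:
    """A uniformly sampled airway pressure / flow stream.

    Attributes
    ----------
    time:
        Sample times in seconds, strictly increasing, spaced ``1/sample_rate``.
    pressure:
        Airway pressure in cmH2O.
    flow:
        Flow in L/s (positive = inspiratory).
    sample_rate:
        Sampling rate in Hz.
    source_id:
        Opaque patient / file identifier.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    sample_rate: float = 50.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.time)
        if not (len(self.pressure) == len(self.flow) == n):
            raise VWDFormatError("time, pressure and flow must have equal length")
        if n < 2:
            raise VWDFormatError("a waveform record needs at least 2 samples")
        dt = np.diff(self.time)
        expected = 1.0 / self.sample_rate
        if np.any(dt <= 0):
            raise VWDFormatError("time must be strictly increasing")
        bad = np.abs(dt - expected) > _SPACING_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise VWDFormatError(
                f"non-uniform sampling at sample {i + 1}: spacing {dt[i]:.6g} s, "
                f"expected {expected:.6g} s"
            )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class GoldStandardAnnotation:
    """Consensus per-breath label record."""

    breath_index: int
    labels: frozenset[str]
    patient_id: str = ""

    def __post_init__(self) -> None:
        unknown = self.labels - ALLOWED_LABELS
        if unknown:
            raise VWDFormatError(f"unknown label token(s): {sorted(unknown)}")
        if "none" in self.labels and len(self.labels) > 1:
            raise VWDFormatError("'none' is exclusive of all other labels")
        if not self.labels:
            raise VWDFormatError("a breath must carry at least one label")


_HEADER_RE = re.compile(r"#.*flow_unit=(?P<unit>L/(?:s|min))(?:\s+sample_rate=(?P<rate>[\d.]+))?")


def read_vwd_file(path: str | Path, dialect: VWDDialect | None = None) -> WaveformRecord:
    """Read a waveform CSV file into a :class:`WaveformRecord`.

    The file's own ``# ventwave-vwd`` header line, when present, overrides the
    dialect's flow unit and sample rate.  Flow is converted to L/s and time is
    re-based to start at zero.
    """
    path = Path(path)
    dialect = dialect or VWDDialect()
    flow_unit = dialect.flow_unit
    sample_rate = dialect.sample_rate

    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        m = _HEADER_RE.search(first)
        if m:
            flow_unit = m.group("unit")
            if m.group("rate"):
                sample_rate = float(m.group("rate"))

    df = pd.read_csv(
        path,
        skiprows=skip,
        header=None,
        names=list(dialect.columns),
        dtype=str,
        skip_blank_lines=False,
    )
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 1 + skip
        raise VWDFormatError(f"{path.name}: malformed row at line {line}")

    time = values["time_s"].to_numpy()
    pressure = values["pressure_cmH2O"].to_numpy()
    flow = flow_to_lps(values["flow"].to_numpy(), flow_unit)
    return WaveformRecord(
        time=time - time[0],
        pressure=pressure,
        flow=flow,
        sample_rate=sample_rate,
        source_id=path.stem,
    )


def write_vwd_file(record: WaveformRecord, path: str | Path, flow_unit: str = "L/s") -> None:
    """Write a :class:`WaveformRecord` to the waveform CSV dialect."""
    path = Path(path)
    flow = flow_from_lps(record.flow, flow_unit)
    with open(path, "w") as fh:
        fh.write(f"# ventwave-vwd flow_unit={flow_unit} sample_rate={record.sample_rate:g}\n")
        for t, p, q in zip(record.time, record.pressure, flow):
            fh.write(f"{t:.8f},{p:.6f},{q:.8f}\n")


def read_gold_standard(path: str | Path) -> list[GoldStandardAnnotation]:
    """Read a gold-standard annotation CSV (``breath_index,patient_id,label``).

    Multiple rows for the same breath are merged into one annotation by set
    union of their labels.  Unknown label tokens raise :class:`VWDFormatError`.
    Extra columns (e.g. simulator truth volumes) are ignored.
    """
    df = pd.read_csv(path)
    required = {"breath_index", "patient_id", "label"}
    if not required.issubset(df.columns):
        raise VWDFormatError(f"annotation file must have columns {sorted(required)}")
    merged: dict[tuple[str, int], set[str]] = {}
    for _, row in df.iterrows():
        key = (str(row["patient_id"]), int(row["breath_index"]))
        merged.setdefault(key, set()).add(str(row["label"]).strip())
    annotations = []
    for (patient, idx), labels in merged.items():
        if "none" in labels and len(labels) > 1:
            labels = labels - {"none"}
        annotations.append(
            GoldStandardAnnotation(breath_index=idx, labels=frozenset(labels), patient_id=patient)
        )
    annotations.sort(key=lambda a: (a.patient_id, a.breath_index))
    return annotations


def write_gold_standard(annotations: list[GoldStandardAnnotation], path: str | Path) -> None:
    """Write annotations in the gold-standard CSV format (one row per label)."""
    rows = []
    for ann in annotations:
        for label in sorted(ann.labels):
            rows.append({"breath_index": ann.breath_index, "patient_id": ann.patient_id, "label": label})
    pd.DataFrame(rows, columns=["breath_index", "patient_id", "label"]).to_csv(path, index=False)


# Column layout of the classification-matrix CSV.  Booleans are stored as 0/1.
_MATRIX_FLOAT_COLS = [
    "tvi", "tve", "i_time", "e_time", "ratio_tve_tvi",
    "pip", "peep", "peak_insp_flow", "peak_exp_flow", "end_exp_flow",
]
_MATRIX_BOOL_COLS = [
    "dta", "dta_partner", "bsa", "suction", "cough", "disconnect",
    "corrected_dta", "corrected_bsa",
]
MATRIX_COLUMNS = ["breath_index", *_MATRIX_FLOAT_COLS, *_MATRIX_BOOL_COLS, "tvv_class"]


def write_classification_matrix(matrix, path: str | Path) -> None:
    """Write a classification matrix to CSV, one row per breath.

    Round-trip via :func:`read_classification_matrix` reproduces flags exactly
    and floats to 1e-6.
    """
    df = matrix.to_frame()
    out = pd.DataFrame()
    out["breath_index"] = df["breath_ordinal"].astype(int)
    for col in _MATRIX_FLOAT_COLS:
        out[col] = df[col].map(lambda v: f"{v:.6f}")
    for col in _MATRIX_BOOL_COLS:
        out[col] = df[col].astype(bool).astype(int)
    out["tvv_class"] = df["tvv_class"].astype(int)
    out.to_csv(path, index=False)


def read_classification_matrix(path: str | Path):
    """Read a classification-matrix CSV back into a :class:`ClassificationMatrix`."""
    from .rules import ClassificationMatrix  # deferred to avoid an import cycle

    df = pd.read_csv(path)
    missing = set(MATRIX_COLUMNS) - set(df.columns)
    if missing:
        raise VWDFormatError(f"classification matrix missing columns {sorted(missing)}")
    df = df.rename(columns={"breath_index": "breath_ordinal"})
    for col in _MATRIX_BOOL_COLS:
        df[col] = df[col].astype(bool)
    df["tvv_class"] = df["tvv_class"].astype(int)
    return ClassificationMatrix(df)
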