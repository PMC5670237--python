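"""Partitioning a continuous waveform into breaths.

A breath begins when flow rises through the trigger threshold ``f_on`` after
having been below the release threshold ``f_off`` (hysteresis, so ringing
around a single threshold cannot double-trigger).  Consecutive breath starts
tile the stream: breath k ends where breath k+1 starts.  The samples before
the first detected start and after the last one are partial breaths and are
excluded.

Within a breath, ``x0`` is the inspiration-to-expiration transition: the
first sample at or after the breath start whose flow is non-positive after a
positive (inspiratory) sample has been seen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vwd_io import WaveformRecord

__all__ = ["SegmentationParams", "Breath", "segment_breaths", "find_x0"]


@dataclass(frozen=True)
class SegmentationParams:
    """Breath-delimitation thresholds.

    Attributes
    ----------
    f_on:
        Trigger flow threshold (L/s); a breath starts when flow rises to
        ``>= f_on``.
    f_off:
        Release threshold (L/s); the trigger re-arms once flow has fallen
        below ``f_off``.
    min_duration_s:
        Minimum breath duration (s); triggers closer than this to the
        previous accepted start are ignored as noise.
    """

    f_on: float = 0.1
    f_off: float = 0.03
    min_duration_s: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.f_off < self.f_on):
            raise ValueError("require 0 < f_off < f_on")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")


@dataclass(frozen=True)
class Breath:
    """One segmented breath: half-open sample interval [start_index, end_index)."""

    start_index: int
    end_index: int
    x0_index: int
    breath_ordinal: int

    def __post_init__(self) -> None:
        if not (self.start_index < self.x0_index <= self.end_index):
            raise ValueError("require start_index < x0_index <= end_index")


def find_x0(record: WaveformRecord, start: "int | Breath", end: int | None = None) -> int:
    """Locate the inspiration→expiration transition within ``[start, end)``.

    Accepts either explicit sample bounds or a :class:`Breath`.  Returns the
    index of the first sample with flow <= 0 that follows at least one
    positive-flow sample; flow exactly zero counts as "inspiration has
    ended".  If flow never crosses, returns ``end``.
    """
    if isinstance(start, Breath):
        start, end = start.start_index, start.end_index
    assert end is not None
    flow = record.flow[start:end]
    seen_positive = False
    for i, q in enumerate(flow):
        if q > 0:
            seen_positive = True
        elif seen_positive:
            return start + i
    return end


def segment_breaths(
    record: WaveformRecord, params: SegmentationParams | None = None
) -> list[Breath]:
    """Segment a waveform record into complete breaths.

    Returns breaths ordered by start, tiling the region between the first and
    last detected trigger.  A record with no two accepted triggers yields an
    empty list.  NaN samples raise ``ValueError``.
    """
    params = params or SegmentationParams()
    flow = record.flow
    if np.isnan(flow).any() or np.isnan(record.pressure).any():
        raise ValueError("record contains NaN samples")

    # Upward crossings of f_on, validated by the hysteresis condition that
    # flow dropped below f_off since the previous accepted start (or since
    # the beginning of the record, for the first start).
    above_on = flow >= params.f_on
    candidates = np.flatnonzero(above_on[1:] & ~above_on[:-1]) + 1

    min_gap = int(round(params.min_duration_s * record.sample_rate))
    starts: list[int] = []
    for idx in candidates:
        idx = int(idx)
        if starts:
            if idx - starts[-1] < min_gap:
                continue
            armed = np.min(flow[starts[-1]:idx]) < params.f_off
        else:
            armed = np.min(flow[:idx]) < params.f_off
        if armed:
            starts.append(idx)

    breaths: list[Breath] = []
    for k in range(len(starts) - 1):
        s, e = starts[k], starts[k + 1]
        x0 = find_x0(record, s, e)
        if x0 == s:  # no positive flow: cannot happen for a trigger-started breath
            x0 = s + 1
        breaths.append(Breath(start_index=s, end_index=e, x0_index=x0, breath_ordinal=k))
    return breaths
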