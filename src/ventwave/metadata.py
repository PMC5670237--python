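"""Per-breath quantitative metadata.

Tidal volumes are computed by integrating the flow-time curve with composite
Simpson's rule (fourth-order accurate).  Inspiratory volume (TVi) is the
integral from the breath start to x0, the inspiration→expiration transition;
expiratory volume (TVe) is the magnitude of the integral from x0 to the
breath end.  All volumes are reported in ml, times in seconds, pressures in
cmH2O, flows in L/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .segmentation import Breath
from .vwd_io import WaveformRecord

__all__ = ["BreathMetadata", "integrate_flow", "compute_breath_metadata"]

#: Number of end-expiratory samples averaged for the PEEP estimate (0.1 s at 50 Hz).
PEEP_WINDOW_SAMPLES = 5


@dataclass(frozen=True)
class BreathMetadata:
    """Derived quantities for one breath.

    ``ratio_tve_tvi`` is TVe/TVi; when TVi is zero the ratio is reported as
    0.0 with ``ratio_undefined`` set.
    """

    tvi: float                 # ml
    tve: float                 # ml, magnitude
    i_time: float              # s
    e_time: float              # s
    ratio_tve_tvi: float       # dimensionless
    pip: float                 # cmH2O
    peep: float                # cmH2O
    peak_insp_flow: float      # L/s
    peak_exp_flow: float       # L/s, magnitude
    end_exp_flow: float        # L/s, signed
    ratio_undefined: bool = False


def integrate_flow(
    flow: np.ndarray, sample_rate: float, start: int = 0, stop: int | None = None
) -> float:
    """Integrate flow (L/s) over the half-open sample span ``[start, stop)``; returns ml.

    Composite Simpson's rule over the span; when the number of intervals is
    odd, Simpson is applied to the even-interval prefix and the final
    interval is closed with the trapezoidal rule.  A span with fewer than two
    samples integrates to 0.
    """
    flow = np.asarray(flow, dtype=float)
    if stop is None:
        stop = len(flow)
    segment = flow[start:stop]
    n = len(segment)
    if n < 2:
        return 0.0
    dx = 1.0 / sample_rate
    intervals = n - 1
    if intervals % 2 == 0:
        litres = simpson(segment, dx=dx)
    else:
        litres = 0.0
        if n > 2:
            litres += simpson(segment[:-1], dx=dx)
        litres += 0.5 * (segment[-2] + segment[-1]) * dx
    return float(litres) * 1000.0


def compute_breath_metadata(record: WaveformRecord, breath: Breath) -> BreathMetadata:
    """Compute :class:`BreathMetadata` for one segmented breath.

    TVi spans ``[start, x0)``; TVe spans ``[x0, end)``.  PIP is the maximum
    pressure over the whole breath; PEEP is the mean pressure over the final
    ``PEEP_WINDOW_SAMPLES`` samples of expiration (or of the breath, if the
    expiratory phase is shorter).  A breath with no expiratory samples
    (x0 = end) gets TVe = 0, E-time = 0 and ratio 0.
    """
    s, x0, e = breath.start_index, breath.x0_index, breath.end_index
    rate = record.sample_rate

    tvi = integrate_flow(record.flow, rate, s, x0)
    tve = abs(integrate_flow(record.flow, rate, x0, e))
    i_time = (x0 - s) / rate
    e_time = (e - x0) / rate

    if tvi > 0:
        ratio = tve / tvi
        undefined = False
    else:
        ratio = 0.0
        undefined = True
    if x0 == e:
        ratio, undefined = 0.0, False if tvi > 0 else undefined

    pressure = record.pressure[s:e]
    pip = float(np.max(pressure))
    tail = record.pressure[max(e - PEEP_WINDOW_SAMPLES, x0 if x0 < e else s):e]
    if len(tail) == 0:
        tail = record.pressure[max(e - PEEP_WINDOW_SAMPLES, s):e]
    peep = float(np.mean(tail))

    insp = record.flow[s:x0]
    exp = record.flow[x0:e]
    peak_insp = float(np.max(insp)) if len(insp) else 0.0
    peak_exp = float(max(0.0, -np.min(exp))) if len(exp) else 0.0
    end_exp = float(record.flow[e - 1])

    return BreathMetadata(
        tvi=tvi,
        tve=tve,
        i_time=i_time,
        e_time=e_time,
        ratio_tve_tvi=ratio,
        pip=pip,
        peep=peep,
        peak_insp_flow=peak_insp,
        peak_exp_flow=peak_exp,
        end_exp_flow=end_exp,
        ratio_undefined=undefined,
    )
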