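"""Single-compartment lung / ventilator simulator with labeled event injection.

The mechanical model is a linear one-compartment lung: resistance R
(cmH2O·s/L), compliance C (ml/cmH2O), expiratory time constant tau = R·C.
Airway pressure follows the equation of motion P = R·Q + V/C + PEEP, and
expiration is passive exponential decay of the trapped volume through R, so
during normal expiration the airway pressure sits exactly at PEEP.

Supported modes:

* **AC/VC** — square (constant) inspiratory flow delivering the set tidal
  volume over the set inspiratory time;
* **AC/PC** — constant inspiratory pressure ``set_pressure`` above PEEP,
  giving exponentially decaying flow (dP/R)·exp(-t/tau).

Every breath ends its inspiration on an explicit zero-flow sample (finite
exhalation-valve slew), which pins the inspiration→expiration transition x0
on the sample grid.  Ground-truth volumes are defined as the trapezoidal
integral of the generated noise-free flow over the truth spans — the
analogue of the volume a ventilator's own software reports from its sampled
flow signal.  Inspiratory flow amplitude is chosen so that this integral
equals the set tidal volume exactly in VC mode.

Event injection edits the generated timeline, never the labels after the
fact, so detector evaluation is non-circular:

* **DTA** — expiration of the first component is truncated after 0.04-0.24 s
  of low patient-limited flow and a second machine breath fires immediately;
  both components are labeled.
* **BSA** — the expiratory window is shortened below two expiratory time
  constants, leaving TVe:TVi < 0.9 with E-time > 0.3 s.
* **disconnect** — circuit pressure collapses to ~0 with near-zero flow for
  1.5-3 s inside a breath's expiration.
* **cough** — a 2-4 L/s expiratory spike (<= 0.2 s) followed by glottic
  interruption of the remaining exhalation.
* **suction** — a run of 3-8 rapid low-amplitude auto-triggered cycles.

All randomness flows from the single cohort seed; identical seeds give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vwd_io import WaveformRecord

__all__ = [
    "VentilatorSettings",
    "PatientModel",
    "CohortSpec",
    "LabeledCohort",
    "simulate_normal_breath",
    "simulate_cohort",
]


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator prescription.

    ``set_tv`` (ml) applies in AC/VC; ``set_pressure`` (cmH2O above PEEP)
    applies in AC/PC.  ``rate`` is breaths/min, ``i_time`` the inspiratory
    time in seconds.
    """

    mode: str = "AC/VC"
    set_tv: float = 500.0
    set_pressure: float = 12.0
    peep: float = 5.0
    rate: float = 20.0
    i_time: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("AC/VC", "AC/PC"):
            raise ValueError(f"unsupported mode {self.mode!r}")
        if self.mode == "AC/VC" and not (100.0 <= self.set_tv <= 1000.0):
            raise ValueError("set_tv must be within [100, 1000] ml")
        if not self.i_time < 60.0 / self.rate:
            raise ValueError("i_time must be shorter than the cycle period")

    @property
    def period(self) -> float:
        return 60.0 / self.rate


@dataclass(frozen=True)
class PatientModel:
    """Single-compartment respiratory mechanics.

    ``resistance`` in cmH2O·s/L, ``compliance`` in ml/cmH2O; the expiratory
    time constant is R·C.  ``noise_sd`` is additive Gaussian noise as a
    fraction of the peak inspiratory drive signal.
    """

    resistance: float = 10.0
    compliance: float = 50.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.compliance <= 0:
            raise ValueError("resistance and compliance must be positive")

    @property
    def tau(self) -> float:
        """Expiratory time constant in seconds."""
        return self.resistance * self.compliance / 1000.0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: breath count, event mix (fractions) and seed."""

    n_breaths: int = 100
    dta_pct: float = 0.0
    bsa_pct: float = 0.0
    artifact_pct: float = 0.0
    settings: VentilatorSettings = field(default_factory=VentilatorSettings)
    patient: PatientModel = field(default_factory=PatientModel)
    seed: int = 0
    patient_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_breaths < 1:
            raise ValueError("n_breaths must be >= 1")
        if min(self.dta_pct, self.bsa_pct, self.artifact_pct) < 0:
            raise ValueError("event fractions must be non-negative")
        if self.dta_pct * 2 + self.bsa_pct + self.artifact_pct > 1.0:
            raise ValueError("event mix exceeds the cohort size")
        if self.dta_pct > 0 and self.n_breaths < 4:
            raise ValueError("DTA injection needs at least 4 breaths")


@dataclass
class LabeledCohort:
    """Simulator output: waveform record plus per-breath ground truth.

    ``truth`` has one row per breath: breath_index, label, tvi, tve (ml,
    trapezoidal integrals of the noise-free flow), start/x0/end sample
    indices and an ``incomplete_exhalation`` flag set when the expiratory
    window is shorter than three time constants.
    """

    record: WaveformRecord
    truth: pd.DataFrame
    patient_id: str = "sim"


_FS = 50.0
_DT = 1.0 / _FS


class _Builder:
    """Accumulates samples and truth rows while tracking trapped volume."""

    def __init__(self, settings: VentilatorSettings, patient: PatientModel):
        self.s = settings
        self.p = patient
        self.flow: list[np.ndarray] = []
        self.pressure: list[np.ndarray] = []
        self.truth: list[dict] = []
        self.n_samples = 0
        self.volume_ml = 0.0  # trapped volume above FRC at PEEP

    # -- primitives ---------------------------------------------------------

    def append(self, flow: np.ndarray, pressure: np.ndarray) -> int:
        start = self.n_samples
        self.flow.append(np.asarray(flow, dtype=float))
        self.pressure.append(np.asarray(pressure, dtype=float))
        self.n_samples += len(flow)
        return start

    def insp_samples(self) -> tuple[np.ndarray, float]:
        """Noise-free inspiratory flow samples ending on the zero-cross sample.

        Returns (flow array incl. terminal zero sample, delivered volume ml).
        The delivered volume is the trapezoidal integral over the samples
        *excluding* the terminal zero (the TVi span [start, x0)).
        """
        s, p = self.s, self.p
        n_i = int(round(s.i_time * _FS))
        if s.mode == "AC/VC":
            q = s.set_tv / 1000.0 / ((n_i - 1) * _DT)  # exact trapezoid = set_tv
            insp = np.full(n_i, q)
        else:
            t = np.arange(n_i) * _DT
            insp = (s.set_pressure / p.resistance) * np.exp(-t / p.tau)
        flow = np.concatenate([insp, [0.0]])
        delivered = float(np.trapezoid(insp, dx=_DT)) * 1000.0
        return flow, delivered

    def insp_pressure(self, flow: np.ndarray, v0_ml: float) -> np.ndarray:
        """Equation-of-motion pressure along an inspiratory flow segment."""
        p = self.p
        vol = v0_ml + np.concatenate([[0.0], np.cumsum(
            0.5 * (flow[1:] + flow[:-1]) * _DT)]) * 1000.0
        return self.s.peep + vol / p.compliance + p.resistance * flow

    def passive_exp(self, n_e: int, v0_ml: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Passive exponential expiration over ``n_e`` samples from volume v0.

        Returns (flow, pressure, exhaled volume ml by trapezoid over the TVe
        span, which includes the preceding zero-cross sample).
        """
        p = self.p
        t = np.arange(1, n_e + 1) * _DT
        flow = -(v0_ml / 1000.0 / p.tau) * np.exp(-t / p.tau)
        # airway pressure is PEEP exactly during passive expiration:
        # V/C cancels R·Q by construction of the time constant
        pressure = np.full(n_e, self.s.peep)
        span = np.concatenate([[0.0], flow])  # zero-cross sample opens the span
        exhaled = float(-np.trapezoid(span, dx=_DT)) * 1000.0
        return flow, pressure, exhaled

    # -- breath generators --------------------------------------------------

    def normal_breath(self, label: str = "none", n_e: int | None = None) -> dict:
        """One machine breath: inspiration, zero-cross, passive expiration."""
        s, p = self.s, self.p
        insp_flow, tvi = self.insp_samples()
        if n_e is None:
            n_e = int(round(s.period * _FS)) - len(insp_flow)
        v_end_insp = self.volume_ml + tvi
        exp_flow, exp_pressure, tve = self.passive_exp(n_e, v_end_insp)

        flow = np.concatenate([insp_flow, exp_flow])
        pressure = np.concatenate(
            [self.insp_pressure(insp_flow, self.volume_ml), exp_pressure]
        )
        start = self.append(flow, pressure)
        x0 = start + len(insp_flow) - 1  # the zero-cross sample
        end = start + len(flow)
        self.volume_ml = v_end_insp - tve
        row = {
            "breath_index": len(self.truth),
            "label": label,
            "tvi": tvi,
            "tve": tve,
            "start_index": start,
            "x0_index": x0,
            "end_index": end,
            "incomplete_exhalation": n_e * _DT < 3.0 * p.tau,
        }
        self.truth.append(row)
        return row

    def dta_pair(self, rng: np.random.Generator) -> None:
        """Double trigger: truncated low-flow exhalation, immediate re-trigger."""
        s = self.s
        insp_flow, tvi = self.insp_samples()
        v_end_insp = self.volume_ml + tvi

        t_trunc = rng.uniform(0.04, 0.24)
        n_t = max(int(round(t_trunc * _FS)) - 1, 1)  # excl. the zero-cross sample
        # exhaled volume is patient-effort limited; cap the implied flow at
        # 1 L/s so a short truncation never looks like a cough spike
        tve_target = rng.uniform(10.0, min(60.0, 1000.0 * n_t * _DT))
        q_exp = -(tve_target / 1000.0) / (n_t * _DT)
        exp_flow = np.full(n_t, q_exp)
        # patient effort holds the lung inflated; airway pressure near PEEP
        exp_pressure = np.full(n_t, s.peep)
        span = np.concatenate([[0.0], exp_flow])
        tve1 = float(-np.trapezoid(span, dx=_DT)) * 1000.0

        flow = np.concatenate([insp_flow, exp_flow])
        pressure = np.concatenate(
            [self.insp_pressure(insp_flow, self.volume_ml), exp_pressure]
        )
        start = self.append(flow, pressure)
        x0 = start + len(insp_flow) - 1
        end = start + len(flow)
        self.volume_ml = v_end_insp - tve1
        self.truth.append({
            "breath_index": len(self.truth), "label": "dta",
            "tvi": tvi, "tve": tve1,
            "start_index": start, "x0_index": x0, "end_index": end,
            "incomplete_exhalation": True,
        })
        # second component: full machine breath exhaling the stacked volume
        self.normal_breath(label="dta")

    def bsa_breath(self, rng: np.random.Generator) -> None:
        """Expiratory window shorter than two time constants: gas trapping."""
        tau = self.p.tau
        t_e = rng.uniform(max(0.35, 0.7 * tau), min(1.9 * tau, 0.9 + 1.0 * tau))
        n_e = max(int(round(t_e * _FS)) - 1, int(round(0.35 * _FS)))
        self.normal_breath(label="bsa", n_e=n_e)

    def cough_breath(self, rng: np.random.Generator) -> None:
        """Expiratory spike then glottic interruption of exhalation."""
        s, p = self.s, self.p
        insp_flow, tvi = self.insp_samples()
        v_end_insp = self.volume_ml + tvi
        n_e = int(round(s.period * _FS)) - len(insp_flow)

        n_pre = int(round(0.10 * _FS))          # passive exhalation before the spike
        n_spike = int(rng.integers(3, 6))       # <= 0.2 s spike
        amp = rng.uniform(2.0, 4.0)
        pre_flow, _, _ = self.passive_exp(n_pre, v_end_insp)
        spike = -amp * np.ones(n_spike)
        n_tail = n_e - n_pre - n_spike
        tail = np.full(n_tail, -0.02)           # glottis closed, small leak

        exp_flow = np.concatenate([pre_flow, spike, tail])
        exp_pressure = np.full(n_e, s.peep)
        flow = np.concatenate([insp_flow, exp_flow])
        pressure = np.concatenate(
            [self.insp_pressure(insp_flow, self.volume_ml), exp_pressure]
        )
        start = self.append(flow, pressure)
        x0 = start + len(insp_flow) - 1
        end = start + len(flow)
        span = np.concatenate([[0.0], exp_flow])
        tve = float(-np.trapezoid(span, dx=_DT)) * 1000.0
        self.volume_ml = 0.0  # the cough empties the lung to FRC
        self.truth.append({
            "breath_index": len(self.truth), "label": "cough",
            "tvi": tvi, "tve": tve,
            "start_index": start, "x0_index": x0, "end_index": end,
            "incomplete_exhalation": False,
        })

    def disconnect_breath(self, rng: np.random.Generator) -> None:
        """Circuit opens mid-expiration: pressure collapses, flow signal dies."""
        s = self.s
        insp_flow, tvi = self.insp_samples()
        v_end_insp = self.volume_ml + tvi

        n_pre = int(round(0.30 * _FS))
        pre_flow, pre_pressure, tve_pre = self.passive_exp(n_pre, v_end_insp)
        t_d = rng.uniform(1.5, 3.0)
        n_d = int(round(t_d * _FS))
        window_flow = np.zeros(n_d)
        window_pressure = np.full(n_d, 0.2)  # residual sensor offset, PEEP lost

        exp_flow = np.concatenate([pre_flow, window_flow])
        exp_pressure = np.concatenate([pre_pressure, window_pressure])
        flow = np.concatenate([insp_flow, exp_flow])
        pressure = np.concatenate(
            [self.insp_pressure(insp_flow, self.volume_ml), exp_pressure]
        )
        start = self.append(flow, pressure)
        x0 = start + len(insp_flow) - 1
        end = start + len(flow)
        span = np.concatenate([[0.0], exp_flow])
        tve = float(-np.trapezoid(span, dx=_DT)) * 1000.0
        self.volume_ml = 0.0  # patient exhales through the open circuit
        self.truth.append({
            "breath_index": len(self.truth), "label": "disconnect",
            "tvi": tvi, "tve": tve,
            "start_index": start, "x0_index": x0, "end_index": end,
            "incomplete_exhalation": False,
        })

    def suction_cycle(self) -> None:
        """One rapid low-amplitude auto-trigger cycle during suctioning."""
        s = self.s
        n_i, n_e = 12, 13
        q_i, q_e = 0.55, -0.08
        insp = np.concatenate([np.full(n_i, q_i), [0.0]])
        exp = np.full(n_e, q_e)
        flow = np.concatenate([insp, exp])
        # small pressure bump around PEEP; the circuit stays pressurised
        bump = 2.5 * np.sin(np.linspace(0.0, np.pi, n_i + 1))
        pressure = np.concatenate([s.peep + bump, np.full(n_e, s.peep)])
        start = self.append(flow, pressure)
        x0 = start + n_i
        end = start + len(flow)
        tvi = float(np.trapezoid(insp[:-1], dx=_DT)) * 1000.0
        tve = float(-np.trapezoid(np.concatenate([[0.0], exp]), dx=_DT)) * 1000.0
        self.truth.append({
            "breath_index": len(self.truth), "label": "suction",
            "tvi": tvi, "tve": tve,
            "start_index": start, "x0_index": x0, "end_index": end,
            "incomplete_exhalation": True,
        })

    def suction_run(self, length: int) -> None:
        for _ in range(length):
            self.suction_cycle()
        self.volume_ml = 0.0  # suctioning empties the airway


def simulate_normal_breath(
    settings: VentilatorSettings,
    patient: PatientModel,
    seed: int = 0,
) -> LabeledCohort:
    """Generate a single artifact-free breath with ground truth.

    A convenience wrapper around :func:`simulate_cohort` with ``n_breaths=1``
    and no events.
    """
    return simulate_cohort(CohortSpec(
        n_breaths=1, settings=settings, patient=patient, seed=seed,
    ))


def _allocate_blocks(spec: CohortSpec, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Deterministic event allocation: exact counts, shuffled placement.

    Returns an ordered list of (kind, n_slots) blocks covering all
    ``spec.n_breaths`` breath slots; every event block is separated by at
    least one normal breath.
    """
    n = spec.n_breaths
    n_dta = int(round(spec.dta_pct * n))
    n_bsa = int(round(spec.bsa_pct * n))
    n_art = int(round(spec.artifact_pct * n))

    blocks: list[tuple[str, int]] = [("dta", 2)] * n_dta + [("bsa", 1)] * n_bsa
    art_left = n_art
    kinds = ["suction", "cough", "disconnect"]
    k = 0
    while art_left > 0:
        kind = kinds[k % 3]
        if kind == "suction":
            length = int(rng.integers(3, 9))
            if length > art_left:
                if art_left >= 3:
                    length = art_left
                else:
                    k += 1
                    continue
            blocks.append(("suction", length))
            art_left -= length
        else:
            blocks.append((kind, 1))
            art_left -= 1
        k += 1

    used = sum(b[1] for b in blocks)
    n_normal = n - used
    if n_normal < len(blocks) + 1:
        raise ValueError("event mix too dense: not enough normal breaths to separate events")

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # distribute normal breaths into len(blocks)+1 gaps, each gap >= 1
    # (leading gap >= 1 also guarantees a clean first trigger)
    n_gaps = len(blocks) + 1
    extra = n_normal - n_gaps
    if n_gaps > 1 and extra > 0:
        cuts = np.sort(rng.integers(0, extra + 1, size=n_gaps - 1))
        gaps = np.diff(np.concatenate([[0], cuts, [extra]])) + 1
    else:
        gaps = np.full(n_gaps, 1 + max(extra, 0) // n_gaps)
        gaps[-1] += n_normal - int(np.sum(gaps))

    plan: list[tuple[str, int]] = []
    for g, block in zip(gaps, blocks):
        plan.extend([("normal", 1)] * int(g))
        plan.append(block)
    plan.extend([("normal", 1)] * int(gaps[-1]))
    assert sum(b[1] for b in plan) == n
    return plan


def simulate_cohort(spec: CohortSpec) -> LabeledCohort:
    """Generate a labeled cohort of breaths with injected events.

    Event fractions are realised exactly (``round(pct * n_breaths)`` breaths
    per class, DTA counted by first components); placement is shuffled by the
    cohort seed.  Additive Gaussian noise at ``patient.noise_sd`` times the
    peak inspiratory drive (flow) / nominal PIP (pressure) is applied to the
    emitted record only; ground truth is computed from the noise-free signal.
    """
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec.settings, spec.patient)

    plan = _allocate_blocks(spec, rng)

    # lead-in: half a second of open circuit at PEEP so the trigger is armed
    n_lead = int(round(0.5 * _FS))
    builder.append(np.zeros(n_lead), np.full(n_lead, spec.settings.peep))

    for kind, length in plan:
        if kind == "normal":
            builder.normal_breath()
        elif kind == "dta":
            builder.dta_pair(rng)
        elif kind == "bsa":
            builder.bsa_breath(rng)
        elif kind == "cough":
            builder.cough_breath(rng)
        elif kind == "disconnect":
            builder.disconnect_breath(rng)
        elif kind == "suction":
            builder.suction_run(length)

    # closing stub: a few inspiratory samples so the last breath is delimited
    insp_flow, _ = builder.insp_samples()
    stub = insp_flow[: min(5, len(insp_flow))]
    stub_pressure = builder.insp_pressure(stub, builder.volume_ml)
    builder.append(stub, stub_pressure)

    flow = np.concatenate(builder.flow)
    pressure = np.concatenate(builder.pressure)

    if spec.patient.noise_sd > 0:
        q_peak = float(np.max(np.abs(builder.insp_samples()[0])))
        p_peak = spec.settings.peep + spec.settings.set_tv / spec.patient.compliance \
            + spec.patient.resistance * q_peak
        flow = flow + rng.normal(0.0, spec.patient.noise_sd * q_peak, size=len(flow))
        pressure = pressure + rng.normal(
            0.0, spec.patient.noise_sd * p_peak, size=len(pressure)
        )

    time = np.arange(len(flow)) * _DT
    record = WaveformRecord(
        time=time, pressure=pressure, flow=flow,
        sample_rate=_FS, source_id=spec.patient_id,
    )
    truth = pd.DataFrame(builder.truth)
    return LabeledCohort(record=record, truth=truth, patient_id=spec.patient_id)


def truth_to_annotations(cohort: LabeledCohort):
    """Convert cohort truth rows into gold-standard annotation objects."""
    from .vwd_io import GoldStandardAnnotation

    return [
        GoldStandardAnnotation(
            breath_index=int(row.breath_index),
            labels=frozenset({row.label}),
            patient_id=cohort.patient_id,
        )
        for row in cohort.truth.itertuples()
    ]
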