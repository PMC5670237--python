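# Methods

## Signals and units

Input is a uniformly sampled stream of airway pressure (cmH2O) and flow
(L/s, positive inspiratory) at 50 Hz — the sampling rate of common
serial-port ventilator captures. The on-disk dialect is a plain CSV
(`time_s, pressure_cmH2O, flow`) with a header comment declaring the flow
unit (`L/s` or `L/min`); flow is converted to L/s on read so that volume
integration is dimensionally direct (L/s × s × 1000 = ml). Volumes are
reported in ml, times in s.

## Breath segmentation

A breath starts when flow rises through the trigger threshold
`seg.f_on` (default 0.1 L/s) after having fallen below the release
threshold `seg.f_off` (0.03 L/s). The hysteresis pair, together with the
minimum breath duration `seg.min_duration_s` (0.2 s), prevents sensor noise
from spawning micro-breaths: at 2% noise on a 0.5 L/s inspiratory signal the
trigger sits ten standard deviations above the noise floor. Consecutive
starts tile the stream (half-open intervals, 0-based), so every sample
between the first and last trigger belongs to exactly one breath; leading
and trailing partial breaths are dropped. Within a breath, x0 — the
inspiration→expiration transition — is the first sample with non-positive
flow after a positive sample; flow exactly 0 counts as "inspiration has
ended", which resolves the discrete-sample boundary deterministically. A
breath whose flow never crosses zero gets x0 = end (no expiratory phase).

Because partial breaths are dropped, segmenting two contiguous chunks
separately and segmenting their concatenation agree on all interior breaths
but the concatenation additionally recovers the breath spanning the seam;
analyses are therefore chunk-agnostic as long as chunks are concatenated
before segmentation.

## Per-breath metadata

TVi is the composite-Simpson integral of flow over [start, x0), TVe the
magnitude of the integral over [x0, end). When a span has an odd number of
intervals, Simpson's rule covers the even prefix and the final interval is
closed with the trapezoidal rule — a deterministic fallback that keeps
fourth-order accuracy almost everywhere. A span under two samples
integrates to zero. PIP is the maximum pressure over the breath; PEEP is
the mean pressure over the final five expiratory samples (0.1 s), the
bedside end-expiratory convention. TVe:TVi is reported as 0 with an
`undefined` flag when TVi is 0.

Two grid caveats are deliberate: (i) phase integrals live on half-open
index spans, so the single interval ending at x0 belongs to neither phase
(worth ~q·dt/2, about 5 ml for a 0.5 L/s breath); (ii) a sampled square
pulse has an irreducible half-sample edge ambiguity, so "1.0 s at 0.5 L/s"
equals 500 ml only when the pulse spans 51 samples. Volume-conservation
checks therefore use span-consistent oracles.

## Classification rules

All thresholds live under `rules.*`. Defaults:

| parameter | default | meaning |
|---|---|---|
| `bsa_ratio_max` | 0.90 | TVe:TVi ceiling for BSA (air trapping) |
| `dta_etime_max` | 0.30 s | E-time ceiling for DTA, floor for BSA |
| `dta_ratio_max` | 0.25 | TVe:TVi ceiling for a DTA first component |
| `dta_tve_max` | 150 ml | exhaled-volume ceiling for DTA |
| `bsa_min_tvi` | 100 ml | minimum TVi for BSA eligibility |
| `disconnect_pressure_max` | 2.0 cmH2O | pressure ceiling during disconnect |
| `disconnect_min_duration` | 1.0 s | minimum sub-threshold window |
| `cough_peak_exp_flow_min` | 1.5 L/s | absolute cough spike floor |
| `cough_peak_ratio_min` | 2.0 | spike vs cohort median peak expiratory flow |
| `suction_min_run` | 3 | consecutive qualifying cycles |
| `suction_amp_max` | 5.0 cmH2O | PIP − PEEP ceiling for a suction cycle |
| `suction_max_duration` | 1.0 s | cycle-duration ceiling for suction |

The shared 0.3 s E-time threshold partitions the expiratory-time axis:
double-triggering shows a non-physiologic (≤ 0.3 s) exhalation with very low
exhaled volume, while breath stacking shows an attempted, physiologic
(> 0.3 s) but incomplete exhalation (TVe:TVi < 90%; ratios at or above 90%
are within flow-sensor imprecision and are deliberately not called events).
Because `dta_ratio_max < bsa_ratio_max` and the E-time ranges are disjoint,
no breath can satisfy both rules; DTA additionally takes precedence, and
DTA partners (the second component breath) are excluded from independent
BSA evaluation. The DTA flag is carried on the first component so each
physiologic event is counted once and fusion can pair components.

Cough detection is intentionally restricted to single-breath high-magnitude
expiratory spikes (both an absolute floor and a cohort-relative multiple);
cough trains are out of scope. Suction is recognized by its run structure —
several consecutive rapid, low-amplitude auto-trigger cycles — so an
isolated small breath is never suction.

## Artifact correction, fusion, grading

Correction implements "a PVA that is also an artifact is not PVA": the
corrected DTA flag is cleared when either component carries any artifact
flag (the event spans both breaths); corrected BSA is cleared when the
breath itself does. Raw flags are preserved so before/after comparisons are
always available; correction can only remove events, never add them, and is
the identity on artifact-free records.

TV-fusion computes each corrected DTA event's effective distending volume
TVi₁ + TVi₂ − TVe₁ (floored at 0); runs of k ≥ 2 consecutive flagged
breaths (triple triggers and longer) fold left-to-right into a single fused
volume Σ TVi − Σ intervening TVe. The fused report grades the first
component's own TVi as the "unfused" comparator and the fused volume once.

TVV grading divides TVi by predicted body weight — the standard
lung-protective reference equations, 45.5 (female) / 50.0 (male) +
0.905·(height_cm − 152.4) — and bins at ≤ 6.5 (class 0, on target),
≤ 8.5 (mild), ≤ 10.5 (moderate), above (severe). The band edges beyond the
6.5 ml/kg target are evenly spaced 2 ml/kg steps and are config-exposed
(`tvv.*`), as is the normalisation subject (default: female at the U.S.
average height of 161.5 cm).

## Statistics

Per-event performance is estimated per patient and pooled with
intercept-only models so that patients, not breaths, are the unit of
clustering:

* sensitivity/specificity/accuracy — binomial GLM on per-patient
  correct-classification proportions with variance weights equal to the
  per-patient gold-standard counts (positives / negatives / total). The
  intercept MLE is exactly the weighted mean of the proportions; the 95% CI
  is formed on the logit scale and transformed back, respecting [0, 1].
  With one patient, or zero between-patient spread, the interval degenerates
  to the point estimate.
* correction effect — per-patient metric differences (corrected − raw),
  intercept-only weighted least squares with the same weights; two-sided
  t-test of the intercept against 0. DTA predictions count both components
  of a pair; a partner counts as corrected-positive only if its first
  component survived correction.
* tidal-volume equivalence — per-condition mean percent differences fitted
  by intercept-only WLS; two one-sided t-tests against a ±10% margin at
  α = 0.05, so equivalence is declared exactly when the 90% CI lies inside
  (−margin, +margin). The margin default mirrors the flow-sensor accuracy
  of the ventilators the dialect emulates.
* TVV shift — integer per-breath class differences (fused − unfused),
  averaged per patient, intercept-only WLS weighted by breaths per patient.

All tests are two-tailed at α = 0.05.

## The lung simulator

The simulator stands in for a calibration-lung bench and for patient
recordings: a linear single-compartment lung with resistance R
(default 10 cmH2O·s/L) and compliance C (50 ml/cmH2O), expiratory time
constant τ = R·C = 0.5 s — mid-range adult mechanics; raising R·C gives a
COPD-like BSA-prone phenotype, lowering C an ARDS-like one. Pressure
follows the equation of motion P = R·Q + V/C + PEEP; passive expiration
decays exponentially with τ, during which airway pressure sits exactly at
PEEP. AC/VC delivers a square inspiratory flow, AC/PC an exponentially
decaying flow (ΔP/R)·e^(−t/τ). Defaults: 500 ml or 12 cmH2O, PEEP 5,
20 breaths/min, I-time 1.0 s.

Every inspiration ends on an explicit zero-flow sample (finite
exhalation-valve slew), pinning x0 on the grid. Ground-truth volumes are
the trapezoidal integrals of the generated noise-free flow over the truth
spans — the analogue of a ventilator's own recorded volume, which is what
bench validations compare against; in VC mode the inspiratory amplitude is
chosen so this integral equals the set TV exactly. Closed-form values agree
with truth to well under 0.5% for PC breaths.

Events are injected by editing the generated timeline (the detectors see
only samples, never labels): DTA truncates expiration after 0.04–0.24 s of
low effort-limited flow (capped at 1 L/s so short truncations never
resemble cough spikes) and immediately fires a second breath; BSA shortens
the expiratory window below two time constants (E-time still > 0.3 s);
disconnect collapses pressure to ~0.2 cmH2O with dead flow for 1.5–3 s;
cough superimposes a 2–4 L/s expiratory spike (≤ 0.2 s) followed by glottic
interruption of the exhalation; suction emits runs of 3–8 rapid
low-amplitude cycles (~120 ml, 0.52 s, ~2.5 cmH2O swing). Event fractions
are realised exactly — round(pct·n) events, DTA counted by first
components — with placement shuffled by the single cohort seed and at
least one normal breath separating events. Trapped volume is carried
across breaths, so post-event breaths exhale the stacked gas.

Noise is additive Gaussian at `noise_sd` (default 2%) of the peak
*inspiratory drive* signal — nominal peak inspiratory flow for the flow
channel, nominal PIP for pressure — rather than of the global waveform
maximum, so a cough spike does not inflate the noise floor past the
segmentation trigger. All randomness derives from the one cohort seed;
identical seeds give bit-identical cohorts.

What the simulator does *not* model — and hence what passing tests do not
show about patient data: active patient effort (muscle pressure) outside
event injection, nonlinear or flow-dependent resistance, leaks and
bronchopleural fistulae, cough trains, ineffective triggering and flow
starvation, mode changes mid-record, and the waveform diversity of real
disease. Detector performance on simulated cohorts demonstrates internal
consistency of rules, correction and statistics under known truth, not
clinical operating characteristics.

## Problem sizes and numerical choices

The bundled validation workloads are desk-scale by design: the
tidal-volume sweep uses 8 conditions × 40 breaths (320 breaths, TVi and
TVe each), and the detector validation 10 simulated patients × 300 breaths
with 8% DTA, 10% BSA, 5% artifacts — large enough that every weighted
estimate rests on hundreds of eligible breaths per class, small enough to
run in seconds. Equality tolerances follow the quantity: exact arithmetic
(fusion, PBW, grading) is asserted to 1e-9, weighted estimators to 1e-6
against closed-form oracles, integration against adaptive quadrature to
0.1%. Ties at rule boundaries are inclusive as documented (E-time ≤ 0.3 s
is DTA-regime; 6.5 ml/kg is on-target; TVe:TVi exactly 0.90 is not BSA).

## Known limitations

Rule thresholds beyond the two anchored ones (the 0.90 ratio and the 0.3 s
E-time split) are package defaults chosen for internal consistency, not
clinically validated constants; they are all config-exposed for
re-derivation against annotated data. The evaluation module assumes gold
annotations align 1:1 with segmented breaths; mismatched segmentations must
be reconciled upstream. The weighted logistic estimator models per-patient
proportions (robust to separation, exact weighted-mean point estimates)
rather than per-breath Bernoulli rows; with a single patient its interval
degenerates to the point estimate.
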