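"""Synthetic neonatal polysomnography cohorts with known pre-event structure.

The generator is phenomenological: breathing-band amplitude/frequency-modulated
oscillators for nasal pressure and respiratory effort, a cardiac-band
oscillator for the photoplethysmogram, and slowly wandering AR(1) baselines
for heart rate, SpO2 and PCO2.  It emulates the regime of overnight infant
recordings (tens of apnea/hypopnea events per hour, lasting a few seconds,
often clustered) without modelling physiology; only the statistical contrasts
a classifier should detect are guaranteed:

* during each event, nasal airflow collapses (and, for central events,
  respiratory effort as well);
* every event is followed by a transient SpO2 desaturation (finished within
  15 s), which is what makes clustered events carry usable history;
* in the ``signature_span_s`` seconds *before* each event onset, a pre-event
  signature is planted whose magnitude scales with ``signature_strength``:
  breathing-amplitude irregularity in NP (strongest) and in THOR/ABD
  (weaker), a proportional SpO2 dip, and a small heart-rate drift.
  ``signature_strength=0`` disables it, making pre-event windows statistically
  indistinguishable from controls.

Everything is reproducible bit-exactly from ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .sigio import ADVERSE_KINDS, Channel, EventAnnotation, Recording

#: native sampling rates emulated by the generator (Hz)
NATIVE_RATES = {
    "NP": 200.0,
    "THOR": 50.0,
    "ABD": 50.0,
    "HR": 1.0,
    "PPG": 100.0,
    "SPO2": 2.0,
    "PCO2": 2.0,
}

_KINDS = (
    "obstructive_apnea",
    "central_apnea",
    "mixed_apnea",
    "obstructive_hypopnea",
    "central_hypopnea",
)
_KIND_P = (0.20, 0.15, 0.10, 0.30, 0.25)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the printed clinical regime at desk scale: 8 infants,
    2 h recordings, ~30 adverse events/h lasting 3-8 s, about a third of
    events followed by another within 60-180 s, pre-event signatures confined
    to the 45 s before onset.
    """

    n_patients: int = 8
    duration_s: float = 7200.0
    event_rate_per_h: float = 30.0
    event_duration_s: tuple[float, float] = (3.0, 8.0)
    cluster_prob: float = 0.35
    cluster_gap_s: tuple[float, float] = (60.0, 180.0)
    #: mean lengths of the alternating active/quiet sleep phases; events occur
    #: only in active phases (overall rate still matches event_rate_per_h)
    active_phase_s: float = 600.0
    quiet_phase_s: float = 480.0
    movement_rate_per_h: float = 10.0
    signature_strength: float = 1.0
    signature_span_s: float = 45.0
    #: modalities carrying a pre-event signature; relative weights are fixed
    #: (NP 1.0, TA 0.5, SPO2/HR proportional dips)
    signature_modalities: tuple[str, ...] = ("NP", "TA", "SPO2", "HR")
    seed: int = 0


@dataclass(frozen=True)
class GTEvent:
    onset_s: float
    end_s: float
    kind: str
    signature_onset_s: float


@dataclass
class GroundTruth:
    """Planted per-event structure, for recovery experiments."""

    patients: dict[str, list[GTEvent]] = field(default_factory=dict)
    signature_span_s: float = 45.0
    signature_modalities: tuple[str, ...] = ("NP", "TA", "SPO2", "HR")


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    e = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    x0 = rng.normal(0.0, sd)
    y, _ = lfilter([1.0], [1.0, -rho], e, zi=[rho * x0])
    return y


def _interval_mask(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    m = np.zeros(t.shape, dtype=bool)
    for a, b in intervals:
        m |= (t >= a) & (t < b)
    return m


def _place_events(
    rng: np.random.Generator, cfg: CohortConfig
) -> list[tuple[float, float, str]]:
    """Clustered two-state renewal process of (onset, end, kind) triples.

    The night alternates between exponentially distributed *active* and
    *quiet* sleep phases; adverse events occur only during active phases
    (a clustered renewal: with probability ``cluster_prob`` an event is
    followed by another after a uniform ``cluster_gap_s`` pause, otherwise
    after a short refractory gap).  The within-active rate is solved so the
    long-run overall rate matches ``event_rate_per_h``, and the quiet phases
    supply the long stretches eligible for control windows, mirroring how
    clinical events concentrate in parts of the night.  No two events are
    closer than 25 s.
    """
    D = cfg.duration_s
    rate = cfg.event_rate_per_h
    if rate <= 0:
        return []
    if D < 120.0:
        raise ValueError("duration too short to host one event")
    p = min(cfg.cluster_prob, 0.95)
    mean_dur = float(np.mean(cfg.event_duration_s))
    mean_gap = float(np.mean(cfg.cluster_gap_s))
    m = 1.0 / (1.0 - p)  # mean cluster size
    span = mean_dur + (m - 1.0) * (mean_gap + mean_dur)  # mean cluster span
    active_frac = cfg.active_phase_s / (cfg.active_phase_s + cfg.quiet_phase_s)
    rate_active = rate / active_frac
    quiet = max(2.0, 3600.0 * m / rate_active - span - 25.0)

    # alternating phase boundaries (gamma, shape 2: less dispersed than
    # exponential so per-patient event counts stay near the configured rate)
    phases: list[tuple[float, float]] = []
    t = rng.gamma(2.0, cfg.quiet_phase_s / 4.0)
    while t < D:
        a = rng.gamma(2.0, cfg.active_phase_s / 2.0)
        phases.append((t, min(t + a, D)))
        t += a + rng.gamma(2.0, cfg.quiet_phase_s / 2.0)

    events: list[tuple[float, float, str]] = []
    for a0, a1 in phases:
        t = max(a0 + rng.exponential(quiet), 30.0)
        while True:
            dur = rng.uniform(*cfg.event_duration_s)
            if t + dur > min(a1, D - 30.0):
                break
            kind = _KINDS[rng.choice(len(_KINDS), p=_KIND_P)]
            events.append((t, t + dur, kind))
            if rng.random() < p:
                t = t + dur + rng.uniform(*cfg.cluster_gap_s)
            else:
                # end-to-onset gaps of [45, 59) s are skipped: such a
                # successor's target window would clear the predecessor's
                # mask yet still contain its desaturation tail
                extra = rng.exponential(quiet)
                if 20.0 <= extra < 34.0:
                    extra += 14.0
                t = t + dur + 25.0 + extra
    return events


def _place_movements(
    rng: np.random.Generator,
    cfg: CohortConfig,
    events: list[tuple[float, float, str]],
) -> list[tuple[float, float]]:
    D = cfg.duration_s
    n = rng.poisson(cfg.movement_rate_per_h * D / 3600.0)
    out: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(20):
            start = rng.uniform(0.0, max(D - 12.0, 1.0))
            dur = rng.uniform(2.0, 10.0)
            end = start + dur
            if all(end < a - 5.0 or start > b + 5.0 for a, b, _ in events):
                out.append((start, end))
                break
    return sorted(out)


def _generate_patient(
    rng: np.random.Generator, cfg: CohortConfig, patient_id: str
) -> tuple[Recording, list[EventAnnotation], list[GTEvent]]:
    D = cfg.duration_s
    events = _place_events(rng, cfg)
    movements = _place_movements(rng, cfg, events)
    strength = cfg.signature_strength
    span = cfg.signature_span_s
    sig_iv = [(max(a - span, 0.0), a) for a, _, _ in events]
    sig_mods = set(cfg.signature_modalities)

    n200 = int(round(D * 200))
    t200 = np.arange(n200) / 200.0

    # respiratory oscillator: slowly wandering frequency around ~0.9 Hz
    f0 = rng.uniform(0.7, 1.1)
    f1hz = f0 * (1.0 + 0.08 * _ar1(rng, int(D) + 2, 0.98, 1.0))
    f200 = np.interp(t200, np.arange(len(f1hz)), np.clip(f1hz, 0.4, 1.6))
    phase200 = 2.0 * np.pi * np.cumsum(f200) / 200.0

    # pre-event breathing irregularity: smoothed multiplicative envelope
    g5 = _ar1(rng, int(D * 5) + 2, 0.9, 1.0)
    g200 = np.interp(t200, np.arange(len(g5)) / 5.0, g5)
    in_sig200 = _interval_mask(t200, sig_iv)

    def sig_env(weight: float, t_mask: np.ndarray, g: np.ndarray) -> np.ndarray:
        env = np.ones_like(g)
        env[t_mask] = np.clip(1.0 + weight * strength * 0.45 * g[t_mask], 0.05, None)
        return env

    # event envelopes: airflow collapses for every event; effort collapses
    # only for central (fully) and mixed (partially) events
    flow_env = np.ones(n200)
    effort_env200 = np.ones(n200)
    for a, b, kind in events:
        m = (t200 >= a) & (t200 < b)
        flow_env[m] = 0.1 if kind.endswith("apnea") else 0.5
        if kind.startswith("central"):
            effort_env200[m] = 0.1
        elif kind.startswith("mixed"):
            effort_env200[m] = 0.4

    move_mask200 = _interval_mask(t200, movements)

    amp_np = 1.0 + 0.15 * np.interp(
        t200, np.arange(int(D) + 2), _ar1(rng, int(D) + 2, 0.99, 1.0)
    )
    np_sig = (
        amp_np
        * flow_env
        * (sig_env(1.0, in_sig200, g200) if "NP" in sig_mods else 1.0)
        * np.sin(phase200)
        + 0.08 * rng.normal(size=n200)
        + 2.5 * rng.normal(size=n200) * move_mask200
    )

    # thoracic + abdominal effort at 50 Hz share the respiratory phase
    sl = slice(None, None, 4)  # 200 Hz -> 50 Hz
    t50, phase50 = t200[sl], phase200[sl]
    eff_env50 = effort_env200[sl]
    in_sig50, g50, move50 = in_sig200[sl], g200[sl], move_mask200[sl]
    ta_env = sig_env(0.4, in_sig50, g50) if "TA" in sig_mods else 1.0
    n50 = len(t50)
    amp_t = 0.9 + 0.12 * np.interp(
        t50, np.arange(int(D) + 2), _ar1(rng, int(D) + 2, 0.99, 1.0)
    )
    thor = (
        amp_t * eff_env50 * ta_env * np.sin(phase50 + 0.25)
        + 0.08 * rng.normal(size=n50)
        + 2.5 * rng.normal(size=n50) * move50
    )
    abd = (
        0.85 * amp_t * eff_env50 * ta_env * np.sin(phase50 + 0.45)
        + 0.08 * rng.normal(size=n50)
        + 2.5 * rng.normal(size=n50) * move50
    )

    # heart rate at 1 Hz: baseline ~140 bpm + slow wander + pre-event drift
    n1 = int(round(D))
    t1 = np.arange(n1, dtype=float)
    hr = 140.0 + rng.uniform(-8, 8) + _ar1(rng, n1, 0.995, 6.0)
    if "HR" in sig_mods:
        for a0, a1 in sig_iv:
            m = (t1 >= a0) & (t1 < a1)
            hr[m] += strength * 3.0 * (t1[m] - a0) / max(a1 - a0, 1.0)
    hr = np.clip(hr, 90.0, 210.0)

    # PPG at 100 Hz: cardiac oscillation driven by the HR trace +
    # respiratory coupling + baseline wander; movement-sensitive
    sl2 = slice(None, None, 2)
    t100, phase_r100, move100 = t200[sl2], phase200[sl2], move_mask200[sl2]
    n100 = len(t100)
    fc100 = np.interp(t100, t1, hr) / 60.0
    phase_c = 2.0 * np.pi * np.cumsum(fc100) / 100.0
    ppg = (
        (1.0 + 0.1 * np.interp(t100, np.arange(int(D) + 2), _ar1(rng, int(D) + 2, 0.99, 1.0)))
        * np.sin(phase_c)
        + 0.25 * np.sin(phase_r100)
        + 0.2 * np.interp(t100, np.arange(int(D) + 2), _ar1(rng, int(D) + 2, 0.999, 1.0))
        + 0.05 * rng.normal(size=n100)
        + 2.5 * rng.normal(size=n100) * move100
    )

    # SpO2 at 2 Hz: baseline ~97% + post-event desaturations (<= 15 s,
    # so they never leak into the next clustered event's pre-window) +
    # pre-event dip proportional to signature strength
    n2 = int(round(D * 2))
    t2 = np.arange(n2) / 2.0
    spo2 = 97.0 + rng.uniform(-1.5, 1.0) + _ar1(rng, n2, 0.999, 0.5)
    hypoxia: list[tuple[float, float]] = []
    for _, b, _kind in events:
        depth = rng.uniform(2.0, 4.5)
        # piecewise shape: 3 s fall, 3 s plateau, 8 s linear recovery
        knots_t = np.array([b, b + 3.0, b + 6.0, b + 14.0])
        knots_v = np.array([0.0, -depth, -depth, 0.0])
        m = (t2 >= b) & (t2 < b + 14.0)
        spo2[m] += np.interp(t2[m], knots_t, knots_v)
        if depth >= 3.0 and b + 14.0 < D:
            hypoxia.append((b + 1.0, b + 13.0))
    if "SPO2" in sig_mods:
        for a0, a1 in sig_iv:
            m = (t2 >= a0) & (t2 < a1)
            spo2[m] -= strength * 1.2 * (t2[m] - a0) / max(a1 - a0, 1.0)
    spo2 = np.clip(spo2, 70.0, 100.0)

    pco2 = np.clip(41.0 + rng.uniform(-2, 2) + _ar1(rng, n2, 0.9995, 1.2), 33.0, 50.0)

    rec = Recording(
        patient_id=patient_id,
        channels={
            "NP": Channel("NP", np_sig, 200.0, "a.u."),
            "THOR": Channel("THOR", thor, 50.0, "a.u."),
            "ABD": Channel("ABD", abd, 50.0, "a.u."),
            "HR": Channel("HR", hr, 1.0, "bpm"),
            "PPG": Channel("PPG", ppg, 100.0, "a.u."),
            "SPO2": Channel("SPO2", spo2, 2.0, "%"),
            "PCO2": Channel("PCO2", pco2, 2.0, "mmHg"),
        },
    )
    annotations = [EventAnnotation(kind, a, b) for a, b, kind in events]
    annotations += [EventAnnotation("movement", a, b) for a, b in movements]
    annotations += [EventAnnotation("hypoxia", a, b) for a, b in hypoxia]
    annotations.sort(key=lambda e: (e.start_s, e.end_s))
    gt = [GTEvent(a, b, kind, max(a - span, 0.0)) for a, b, kind in events]
    return rec, annotations, gt


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[list[Recording], list[list[EventAnnotation]], GroundTruth]:
    """Generate ``cfg.n_patients`` synthetic recordings with annotations.

    Deterministic: the same config yields bit-identical output.
    """
    root = np.random.SeedSequence(cfg.seed)
    gt = GroundTruth(
        signature_span_s=cfg.signature_span_s,
        signature_modalities=cfg.signature_modalities,
    )
    recordings, ann_lists = [], []
    for i, child in enumerate(root.spawn(cfg.n_patients)):
        pid = f"synthetic-{cfg.seed}-{i:02d}"
        rec, anns, events = _generate_patient(np.random.default_rng(child), cfg, pid)
        recordings.append(rec)
        ann_lists.append(anns)
        gt.patients[pid] = events
    return recordings, ann_lists, gt


def cohort_summary(
    ann_lists: list[list[EventAnnotation]],
    duration_s: float,
    recordings: list[Recording] | None = None,
    windowing_cfg=None,
) -> pd.DataFrame:
    """Per-patient descriptive statistics of an annotated cohort.

    Reports adverse events per hour and the median event duration; when
    recordings are supplied, also the target/control window counts produced
    by :func:`namts.windowing.extract_windows` (with ``windowing_cfg`` or its
    defaults).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rows = []
    for i, anns in enumerate(ann_lists):
        adverse = [a for a in anns if a.kind in ADVERSE_KINDS]
        row = {
            "patient": recordings[i].patient_id if recordings else i,
            "events_per_h": len(adverse) * 3600.0 / duration_s,
            "median_event_duration_s": (
                float(np.median([a.duration_s for a in adverse])) if adverse else 0.0
            ),
            "n_events": len(adverse),
        }
        if recordings is not None:
            from .windowing import WindowingConfig, extract_windows

            wcfg = windowing_cfg or WindowingConfig()
            windows = extract_windows(recordings[i], anns, wcfg)
            row["n_target_windows"] = sum(w.label == "target" for w in windows)
            row["n_control_windows"] = sum(w.label == "control" for w in windows)
        rows.append(row)
    return pd.DataFrame(rows)
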