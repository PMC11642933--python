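"""Window preprocessing: decimation, standardization, range normalization.

Each raw window is turned into a fixed-shape :class:`ModelInput` with six
modalities:

* ``NP`` — nasal pressure, decimated to 5 Hz, z-scored per window;
* ``TA`` — thoracic + abdominal effort: each trace decimated to 5 Hz and
  z-scored, summed pointwise, and the sum z-scored again;
* ``PPG`` — photoplethysmogram, decimated to 5 Hz, z-scored per window;
* ``HR`` — heart rate, left at 1 Hz, range-normalized from [50, 240] bpm
  to [-1, 1];
* ``SPO2`` — decimated 2 -> 1 Hz, range-normalized from [60, 100] %;
* ``PCO2`` — decimated 2 -> 1 Hz, range-normalized from [30, 70] mmHg.

Decimation is anti-aliased with an order-8 Chebyshev type-I low-pass
(0.01 dB passband ripple, cutoff 0.8x the target Nyquist) applied forward and
backward (zero phase, so pre-event signatures are not shifted in time) and
rescaled to exact unit DC gain; the low ripple keeps in-band sinusoids
accurate to well under 1% through multiple stages.  Large factors are
decomposed into integer stages of at most 10.  No other cleaning or
imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import cheby1, filtfilt

from .windowing import RawWindow

#: modality order used for flat feature vectors
MODALITIES = ("NP", "TA", "PPG", "HR", "SPO2", "PCO2")

#: model-input sampling rate per modality (Hz)
MODEL_RATES = {"NP": 5.0, "TA": 5.0, "PPG": 5.0, "HR": 1.0, "SPO2": 1.0, "PCO2": 1.0}

#: physiologic range-normalization bounds (lo, hi) for the slow modalities
RANGE_BOUNDS = {"HR": (50.0, 240.0), "SPO2": (60.0, 100.0), "PCO2": (30.0, 70.0)}

_ZERO_VAR_GUARD = 1e-12


def modality_lengths(window_len_s: float = 30.0) -> dict[str, int]:
    return {m: int(round(window_len_s * MODEL_RATES[m])) for m in MODALITIES}


def modality_slices(window_len_s: float = 30.0) -> dict[str, slice]:
    """Column slices of each modality in the flat stacked vector."""
    out, off = {}, 0
    for m, n in modality_lengths(window_len_s).items():
        out[m] = slice(off, off + n)
        off += n
    return out


def n_features(window_len_s: float = 30.0) -> int:
    return sum(modality_lengths(window_len_s).values())


def _stage_factors(q: int) -> list[int]:
    """Decompose an integer decimation factor into stages of at most 10."""
    stages = []
    while q > 10:
        for f in range(10, 1, -1):
            if q % f == 0:
                stages.append(f)
                q //= f
                break
        else:  # prime > 10: no exact staging possible
            raise ValueError(f"cannot stage decimation factor {q}")
    stages.append(q)
    return stages


def decimate(x: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    """Anti-aliased integer-factor decimation with exact DC preservation."""
    if out_rate > in_rate:
        raise ValueError("out_rate must not exceed in_rate")
    ratio = in_rate / out_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"non-integer decimation ratio {ratio}")
    x = np.asarray(x, dtype=np.float64)
    if q == 1:
        return x.copy()
    if x.size and np.ptp(x) == 0.0:  # constants pass through exactly
        n = len(x)
        for f in _stage_factors(q):
            n = -(-n // f)
        return np.full(n, x[0])
    for f in _stage_factors(q):
        b, a = cheby1(8, 0.01, 0.8 / f)
        b = b * (np.sum(a) / np.sum(b))  # unit gain at DC
        x = filtfilt(b, a, x)[::f]
    return x


def zscore(x: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with population sd; all zeros if sd vanishes."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    sd = x.std()
    if sd < _ZERO_VAR_GUARD:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def sum_effort(thor: np.ndarray, abd: np.ndarray) -> np.ndarray:
    """Standardized sum of the standardized thoracic and abdominal traces."""
    thor, abd = np.asarray(thor), np.asarray(abd)
    if thor.shape != abd.shape:
        raise ValueError("thor and abd must have equal length")
    return zscore(zscore(thor) + zscore(abd))


def range_normalize(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clamp to [lo, hi], then map affinely onto [-1, 1]."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    x = np.clip(np.asarray(x, dtype=np.float64), lo, hi)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


@dataclass
class ModelInput:
    """Fixed-shape model input for one window (150/150/150/30/30/30 at 30 s)."""

    NP: np.ndarray
    TA: np.ndarray
    PPG: np.ndarray
    HR: np.ndarray
    SPO2: np.ndarray
    PCO2: np.ndarray
    label: int  # 1 = target, 0 = control
    patient_id: str = ""
    start_s: float = 0.0
    horizon_s: float = 15.0

    def __getitem__(self, modality: str) -> np.ndarray:
        return getattr(self, modality)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, m) for m in MODALITIES])


def prepare_window(w: RawWindow) -> ModelInput:
    """Preprocess one raw window into a :class:`ModelInput`."""
    for name in ("NP", "THOR", "ABD", "HR", "PPG", "SPO2", "PCO2"):
        if name not in w.channels:
            raise ValueError(f"missing channel {name}")
        if np.isnan(w.channels[name]).any():
            raise ValueError(f"channel {name} contains NaN")
    win_len = w.end_s - w.start_s
    lengths = modality_lengths(win_len)

    np_sig = zscore(decimate(w.channels["NP"], w.rates["NP"], 5.0))
    thor = decimate(w.channels["THOR"], w.rates["THOR"], 5.0)
    abd = decimate(w.channels["ABD"], w.rates["ABD"], 5.0)
    ta = sum_effort(thor, abd)
    ppg = zscore(decimate(w.channels["PPG"], w.rates["PPG"], 5.0))
    hr = range_normalize(
        decimate(w.channels["HR"], w.rates["HR"], 1.0), *RANGE_BOUNDS["HR"]
    )
    spo2 = range_normalize(
        decimate(w.channels["SPO2"], w.rates["SPO2"], 1.0), *RANGE_BOUNDS["SPO2"]
    )
    pco2 = range_normalize(
        decimate(w.channels["PCO2"], w.rates["PCO2"], 1.0), *RANGE_BOUNDS["PCO2"]
    )
    m = ModelInput(
        NP=np_sig, TA=ta, PPG=ppg, HR=hr, SPO2=spo2, PCO2=pco2,
        label=1 if w.label == "target" else 0,
        patient_id=w.patient_id, start_s=w.start_s, horizon_s=w.horizon_s,
    )
    for name in MODALITIES:
        if len(m[name]) != lengths[name]:
            raise ValueError(
                f"{name}: expected {lengths[name]} samples, got {len(m[name])}"
            )
    return m


def stack_inputs(
    inputs: list[ModelInput],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack ModelInputs into (X, y, groups) arrays for the estimators."""
    if not inputs:
        raise ValueError("no inputs")
    X = np.stack([m.to_vector() for m in inputs])
    y = np.array([m.label for m in inputs], dtype=np.int64)
    groups = np.array([m.patient_id for m in inputs])
    return X, y, groups
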