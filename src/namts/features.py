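"""The 24 engineered features used by the classical baseline classifiers.

For each of the three oscillatory modalities (NP, TA, PPG), six features:
time-domain skewness and excess kurtosis, plus the centroid, spread, skewness
and kurtosis of the power spectrum (periodogram of the real FFT, DC bin
excluded, normalized to a probability distribution over frequency).  For each
of the three slow modalities (HR, SPO2, PCO2), two features: mean and range
(max minus min).

Conventions (test-pinned): time-domain moments are population moments with
*excess* kurtosis; spectral kurtosis is the *raw* standardized fourth moment
of the spectral distribution.  Degenerate inputs (constant signals, spectral
spread below 1e-12) return zeros instead of NaNs.
"""

from __future__ import annotations

import numpy as np

from .preprocess import MODALITIES, MODEL_RATES, ModelInput, modality_slices

_OSC = ("NP", "TA", "PPG")
_SLOW = ("HR", "SPO2", "PCO2")
_OSC_FEATS = (
    "time_skew",
    "time_kurt",
    "spec_centroid",
    "spec_spread",
    "spec_skew",
    "spec_kurt",
)

#: canonical order of the 24 feature names
FEATURE_NAMES = tuple(
    [f"{m}_{f}" for m in _OSC for f in _OSC_FEATS]
    + [f"{m}_{f}" for m in _SLOW for f in ("mean", "range")]
)

_GUARD = 1e-12


def time_moments(x: np.ndarray) -> tuple[float, float]:
    """Population skewness and excess kurtosis; (0, 0) for constant input."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    if sd < _GUARD:
        return 0.0, 0.0
    z = (x - x.mean()) / sd
    return float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


def spectral_moments(x: np.ndarray, rate: float) -> tuple[float, float, float, float]:
    """Centroid, spread, skewness and raw kurtosis of the power spectrum.

    The spectrum is the squared magnitude of the real FFT with the DC bin
    excluded, normalized to sum to one.  All-zero signals and degenerate
    (single-line) spectra trip guards and return zeros for the undefined
    moments.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 8:
        raise ValueError("need at least 8 samples")
    p = np.abs(np.fft.rfft(x)[1:]) ** 2
    total = p.sum()
    if total < _GUARD:
        return 0.0, 0.0, 0.0, 0.0
    p = p / total
    f = np.fft.rfftfreq(len(x), d=1.0 / rate)[1:]
    centroid = float(np.sum(f * p))
    var = float(np.sum((f - centroid) ** 2 * p))
    spread = np.sqrt(max(var, 0.0))
    if spread < _GUARD:
        return centroid, 0.0, 0.0, 0.0
    z = (f - centroid) / spread
    return centroid, spread, float(np.sum(z**3 * p)), float(np.sum(z**4 * p))


def slow_features(x: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and range (max minus min)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    return float(x.mean()), float(x.max() - x.min())


def featurize(m: ModelInput) -> np.ndarray:
    """24-vector of engineered features in the :data:`FEATURE_NAMES` order."""
    vals = []
    for mod in _OSC:
        ts, tk = time_moments(m[mod])
        sc, ss, sk, sku = spectral_moments(m[mod], MODEL_RATES[mod])
        vals += [ts, tk, sc, ss, sk, sku]
    for mod in _SLOW:
        vals += list(slow_features(m[mod]))
    return np.asarray(vals, dtype=np.float64)


def featurize_matrix(X: np.ndarray, window_len_s: float = 30.0) -> np.ndarray:
    """Featurize stacked model-input rows (as produced by ``stack_inputs``)."""
    sl = modality_slices(window_len_s)
    out = np.empty((len(X), len(FEATURE_NAMES)))
    for i, row in enumerate(np.asarray(X, dtype=np.float64)):
        vals = []
        for mod in _OSC:
            ts, tk = time_moments(row[sl[mod]])
            vals += [ts, tk, *spectral_moments(row[sl[mod]], MODEL_RATES[mod])]
        for mod in _SLOW:
            vals += list(slow_features(row[sl[mod]]))
        out[i] = vals
    return out
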