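"""Extraction of labeled 30 s target/control windows from annotated recordings.

Labeling scheme
---------------
All five apnea/hypopnea kinds are merged into one *adverse event* class.
Signal annotated as adverse event or movement is masked out.  Isolated
intermittent hypoxia (desaturation) annotations are neither masked nor
adverse.  A *target* window ends ``horizon_s`` seconds before an adverse
event onset (default 15 s, i.e. the window covers ``[onset-45, onset-15)``);
a *control* window lies, in every point, at least ``control_buffer_s``
(default 180 s) away from the start and end of every adverse event.

Targets are anchored per event, processed in time order; a candidate that
falls outside the recording, intersects the mask, or overlaps an earlier
target is dropped.  Controls tile each maximal eligible region left-to-right
with non-overlapping windows (a leftover tail shorter than one window is
discarded).  Windows containing any NaN sample are dropped rather than
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sigio import ADVERSE_KINDS, EventAnnotation, Recording

Interval = tuple[float, float]


@dataclass(frozen=True)
class WindowingConfig:
    window_len_s: float = 30.0
    horizon_s: float = 15.0
    control_buffer_s: float = 180.0
    adverse_kinds: frozenset[str] = ADVERSE_KINDS
    mask_kinds: frozenset[str] = frozenset(ADVERSE_KINDS | {"movement"})

    def __post_init__(self) -> None:
        if self.window_len_s <= 0:
            raise ValueError("window_len_s must be positive")
        if self.horizon_s < 0:
            raise ValueError("horizon_s must be non-negative")


@dataclass
class RawWindow:
    """One labeled window with per-channel raw slices at native rates."""

    patient_id: str
    start_s: float
    end_s: float
    label: str  # "target" | "control"
    horizon_s: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted disjoint list."""
    out: list[Interval] = []
    for a, b in sorted(i for i in intervals if i[1] > i[0]):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _complement(intervals: list[Interval], duration_s: float) -> list[Interval]:
    out, cursor = [], 0.0
    for a, b in intervals:
        if a > cursor:
            out.append((cursor, min(a, duration_s)))
        cursor = max(cursor, b)
        if cursor >= duration_s:
            break
    if cursor < duration_s:
        out.append((cursor, duration_s))
    return [iv for iv in out if iv[1] > iv[0]]


def _intersects(a: float, b: float, intervals: list[Interval]) -> bool:
    return any(a < y and x < b for x, y in intervals)


def build_mask(
    annotations: list[EventAnnotation],
    cfg: WindowingConfig,
    duration_s: float,
) -> list[Interval]:
    """Merged, clipped union of all intervals whose kind is masked."""
    ivs = [
        (max(a.start_s, 0.0), min(a.end_s, duration_s))
        for a in annotations
        if a.kind in cfg.mask_kinds
    ]
    return merge_intervals(ivs)


def _slice_window(
    recording: Recording, start_s: float, win_len_s: float
) -> dict[str, np.ndarray] | None:
    """Per-channel raw slices; None if out of bounds or containing NaN."""
    out = {}
    for name, ch in recording.channels.items():
        i0 = int(round(start_s * ch.rate))
        n = int(round(win_len_s * ch.rate))
        if i0 < 0 or i0 + n > len(ch.samples):
            return None
        sl = ch.samples[i0 : i0 + n]
        if np.isnan(sl).any():
            return None
        out[name] = sl.copy()
    return out


def extract_windows(
    recording: Recording,
    annotations: list[EventAnnotation],
    cfg: WindowingConfig = WindowingConfig(),
) -> list[RawWindow]:
    """Emit all target and control windows for one recording."""
    D = recording.duration_s
    W = cfg.window_len_s
    if D < W:
        return []
    mask = build_mask(annotations, cfg, D)
    adverse = sorted(
        (a for a in annotations if a.kind in cfg.adverse_kinds),
        key=lambda a: a.start_s,
    )
    rates = {n: c.rate for n, c in recording.channels.items()}
    windows: list[RawWindow] = []

    # targets: per-event anchoring, earlier events win on overlap
    emitted: list[Interval] = []
    for ev in adverse:
        a = ev.start_s - cfg.horizon_s - W
        b = ev.start_s - cfg.horizon_s
        if a < 0 or b > D:
            continue
        if _intersects(a, b, mask) or _intersects(a, b, emitted):
            continue
        sl = _slice_window(recording, a, W)
        if sl is None:
            continue
        emitted.append((a, b))
        windows.append(RawWindow(recording.patient_id, a, b, "target", cfg.horizon_s, sl, rates))

    # controls: tile maximal regions >= buffer away from every event boundary
    forbidden = merge_intervals(
        mask
        + [
            (ev.start_s - cfg.control_buffer_s, ev.end_s + cfg.control_buffer_s)
            for ev in adverse
        ]
    )
    for a, b in _complement(forbidden, D):
        n = int(np.floor((b - a) / W + 1e-9))
        for i in range(n):
            s = a + i * W
            sl = _slice_window(recording, s, W)
            if sl is None:
                continue
            windows.append(
                RawWindow(recording.patient_id, s, s + W, "control", cfg.horizon_s, sl, rates)
            )
    return windows


def sweep_horizon(
    recording: Recording,
    annotations: list[EventAnnotation],
    cfg: WindowingConfig,
    horizons: list[float],
) -> dict[float, list[RawWindow]]:
    """Re-extract windows for each prediction horizon.

    Controls do not depend on the horizon and are identical across entries.
    """
    from dataclasses import replace

    return {
        h: extract_windows(recording, annotations, replace(cfg, horizon_s=h))
        for h in horizons
    }
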