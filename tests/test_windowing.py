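"""Window extraction against worked examples and a brute-force oracle."""

from dataclasses import replace

import numpy as np
import pytest

from namts.sigio import Channel, EventAnnotation, Recording
from namts.windowing import (
    WindowingConfig,
    build_mask,
    extract_windows,
    merge_intervals,
    sweep_horizon,
)

CFG = WindowingConfig()  # 30 s windows, 15 s horizon, 180 s buffer


def toy_recording(duration_s: float, patient: str = "p") -> Recording:
    rates = {"NP": 2.0, "THOR": 2.0, "ABD": 2.0, "HR": 1.0, "PPG": 2.0,
             "SPO2": 2.0, "PCO2": 1.0}
    return Recording(patient, {
        n: Channel(n, np.zeros(int(duration_s * r)), r) for n, r in rates.items()
    })


def brute_force_windows(duration_s, annotations, cfg, grid=0.5):
    """Independent O(n^2) oracle: test every grid point / candidate window."""
    adverse = [a for a in annotations if a.kind in cfg.adverse_kinds]
    masked = [(a.start_s, a.end_s) for a in annotations if a.kind in cfg.mask_kinds]

    def hits_mask(lo, hi):
        return any(lo < b and a < hi for a, b in masked)

    targets = []
    for ev in sorted(adverse, key=lambda a: a.start_s):
        lo = ev.start_s - cfg.horizon_s - cfg.window_len_s
        hi = ev.start_s - cfg.horizon_s
        if lo < 0 or hi > duration_s or hits_mask(lo, hi):
            continue
        if any(lo < t_hi and t_lo < hi for t_lo, t_hi in targets):
            continue
        targets.append((lo, hi))

    # controls: every point of the window must be eligible (unmasked and at
    # distance >= buffer from every adverse boundary); regions are found by a
    # pointwise grid scan and tiled left-to-right with directly validated
    # windows (the grid must resolve all annotation times)
    buf = cfg.control_buffer_s
    pts = np.arange(0.0, duration_s, grid)
    ok = np.ones(len(pts), dtype=bool)
    for a, b in masked:
        ok &= ~((pts >= a) & (pts < b))
    for ev in adverse:
        ok &= ~((pts > ev.start_s - buf) & (pts < ev.end_s + buf))

    def window_ok(s):
        e = s + cfg.window_len_s
        if e > duration_s or hits_mask(s, e):
            return False
        return all(not (s < ev.end_s + buf and e > ev.start_s - buf)
                   for ev in adverse)

    controls = []
    for i in range(len(pts)):
        if ok[i] and (i == 0 or not ok[i - 1]):  # start of a maximal region
            s = pts[i]
            while window_ok(s):
                controls.append((s, s + cfg.window_len_s))
                s += cfg.window_len_s
    return targets, controls


def _as_sets(windows):
    t = {(round(w.start_s, 6), round(w.end_s, 6)) for w in windows
         if w.label == "target"}
    c = {(round(w.start_s, 6), round(w.end_s, 6)) for w in windows
         if w.label == "control"}
    return t, c


def test_worked_example_single_event():
    rec = toy_recording(1000.0)
    anns = [EventAnnotation("obstructive_apnea", 500.0, 505.0)]
    windows = extract_windows(rec, anns, CFG)
    targets, controls = _as_sets(windows)
    assert targets == {(455.0, 485.0)}
    assert len(controls) == 20
    assert {c[0] for c in controls} == (
        {30.0 * k for k in range(10)} | {685.0 + 30.0 * k for k in range(10)}
    )


def test_event_too_early_yields_no_target():
    rec = toy_recording(400.0)
    anns = [EventAnnotation("central_apnea", 30.0, 34.0)]
    assert not [w for w in extract_windows(rec, anns, CFG) if w.label == "target"]


def test_clustered_events_keep_earlier_target():
    rec = toy_recording(1200.0)
    anns = [EventAnnotation("obstructive_apnea", 600.0, 605.0),
            EventAnnotation("obstructive_apnea", 620.0, 625.0)]
    targets, _ = _as_sets(extract_windows(rec, anns, CFG))
    assert targets == {(555.0, 585.0)}


def test_build_mask_merges_and_ignores_hypoxia():
    anns = [EventAnnotation("obstructive_apnea", 10, 14),
            EventAnnotation("central_hypopnea", 12, 20)]
    assert build_mask(anns, CFG, 100.0) == [(10.0, 20.0)]
    assert build_mask([EventAnnotation("hypoxia", 5, 9)], CFG, 100.0) == []
    assert build_mask([EventAnnotation("movement", 0, 5)], CFG, 100.0) == [(0.0, 5.0)]


def test_hypoxia_not_adverse_for_controls():
    rec = toy_recording(600.0)
    anns = [EventAnnotation("hypoxia", 300.0, 310.0)]
    windows = extract_windows(rec, anns, CFG)
    assert all(w.label == "control" for w in windows)
    assert len(windows) == 20  # full tiling of [0, 600)


def test_window_shapes_and_channel_lengths(mini_recording):
    rec, anns = mini_recording
    windows = extract_windows(rec, anns, CFG)
    assert windows
    for w in windows:
        assert abs((w.end_s - w.start_s) - CFG.window_len_s) < 1e-9
        for name, sl in w.channels.items():
            assert len(sl) == int(round(CFG.window_len_s * w.rates[name]))


def test_nan_windows_dropped():
    rec = toy_recording(600.0)
    rec["NP"].samples[100] = np.nan  # sample at t=50 s
    windows = extract_windows(rec, [], CFG)
    assert all(not (w.start_s <= 50.0 < w.end_s) for w in windows)
    assert len(windows) == 19


def test_sweep_horizon_examples():
    rec = toy_recording(1000.0)
    anns = [EventAnnotation("obstructive_apnea", 500.0, 505.0)]
    out = sweep_horizon(rec, anns, CFG, [0.0, 15.0])
    t0, c0 = _as_sets(out[0.0])
    t15, c15 = _as_sets(out[15.0])
    assert t0 == {(470.0, 500.0)} and t15 == {(455.0, 485.0)}
    assert c0 == c15  # controls do not depend on the horizon
    # horizon larger than available history
    rec2 = toy_recording(400.0)
    anns2 = [EventAnnotation("obstructive_apnea", 350.0, 355.0)]
    out2 = sweep_horizon(rec2, anns2, CFG, [600.0])
    assert not [w for w in out2[600.0] if w.label == "target"]
    assert sweep_horizon(rec, anns, CFG, []) == {}


@pytest.mark.parametrize("seed", range(10))
def test_random_timelines_match_brute_force_oracle(seed):
    """Equivalence with the pointwise oracle on randomized toy timelines."""
    rng = np.random.default_rng(seed)
    for rep in range(12):
        duration = float(rng.integers(400, 1500))
        kinds = ["obstructive_apnea", "central_apnea", "obstructive_hypopnea",
                 "movement", "hypoxia"]
        anns = []
        for _ in range(rng.integers(1, 12)):
            start = float(rng.integers(0, int(duration) - 20)) + 0.5 * rng.integers(0, 2)
            dur = float(rng.integers(3, 15))
            anns.append(EventAnnotation(str(rng.choice(kinds)), start, start + dur))
        cfg = replace(CFG, horizon_s=float(rng.choice([0.0, 15.0, 60.0])))
        got_t, got_c = _as_sets(extract_windows(toy_recording(duration), anns, cfg))
        exp_t, exp_c = brute_force_windows(duration, anns, cfg)
        assert got_t == {(round(a, 6), round(b, 6)) for a, b in exp_t}
        assert got_c == {(round(a, 6), round(b, 6)) for a, b in exp_c}
        # structural invariants
        assert len(got_t) <= sum(a.kind in cfg.adverse_kinds for a in anns)
        starts = sorted(s for s, _ in got_c)
        assert all(b - a >= cfg.window_len_s - 1e-9
                   for a, b in zip(starts, starts[1:]))


def test_merge_intervals():
    assert merge_intervals([(5, 7), (1, 3), (2, 4)]) == [(1, 4), (5, 7)]
    assert merge_intervals([]) == []
    assert merge_intervals([(1, 1)]) == []
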