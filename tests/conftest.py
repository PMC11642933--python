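"""Shared fixtures: tiny synthetic cohorts and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from namts.synthgen import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 patients x 25 min, strong signatures — fast but fully featured."""
    cfg = CohortConfig(n_patients=3, duration_s=1500.0, seed=42)
    recordings, ann_lists, gt = generate_cohort(cfg)
    return cfg, recordings, ann_lists, gt


@pytest.fixture(scope="session")
def mini_recording(tiny_cohort):
    _, recordings, ann_lists, _ = tiny_cohort
    return recordings[0], ann_lists[0]


def write_minimal_edf(path: Path, signals: dict[str, np.ndarray], rate: int,
                      duration_s: int) -> None:
    """Write a synthetic single-record EDF file (int16, physical = digital
    scaled).  Test helper only — just enough of the format for readers."""
    labels = list(signals)
    ns = len(labels)
    header = (
        b"0       "
        + b"synthetic test patient".ljust(80)
        + b"synthetic test recording".ljust(80)
        + b"01.01.20" + b"00.00.00"
        + str(256 * (1 + ns)).encode().ljust(8)
        + b" " * 44
        + b"1       "  # one data record
        + str(duration_s).encode().ljust(8)
        + str(ns).encode().ljust(4)
    )
    phys_min, phys_max = -10.0, 10.0
    dig_min, dig_max = -32768, 32767
    per = lambda vals, w: b"".join(str(v).encode().ljust(w) for v in vals)
    header += per(labels, 16)
    header += per([""] * ns, 80)  # transducer
    header += per(["au"] * ns, 8)
    header += per([phys_min] * ns, 8)
    header += per([phys_max] * ns, 8)
    header += per([dig_min] * ns, 8)
    header += per([dig_max] * ns, 8)
    header += per([""] * ns, 80)  # prefiltering
    header += per([rate * duration_s] * ns, 8)
    header += b" " * (32 * ns)
    body = b""
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    for name in labels:
        x = np.clip(signals[name], phys_min, phys_max)
        dig = np.round((x - phys_min) * scale + dig_min).astype("<i2")
        body += dig.tobytes()
    path.write_bytes(header + body)
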