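"""Reading and writing multichannel recordings and event annotation tracks.

Canonical channel vocabulary
----------------------------
Seven raw channels feed the six model modalities (thoracic and abdominal
effort are later summed into one):

====== ==============================================  typical rate
NP     nasal pressure (airflow)                        200 Hz
THOR   thoracic respiratory effort (RIP)               50 Hz
ABD    abdominal respiratory effort (RIP)              50 Hz
HR     beat-to-beat heart rate (derived from EKG)      1 Hz
PPG    photoplethysmogram                              100 Hz
SPO2   oxygen saturation                               2 Hz
PCO2   transcutaneous CO2 partial pressure             2 Hz
====== ==============================================  typical rate

Two dialects are supported: ``edf`` (read-only, via :mod:`mne`) and a plain-text
``fixture_csv`` dialect which is the bit-exact reference format used by the
synthetic cohort generator and the test-suite: one CSV per channel
(``<patient>/<CHANNEL>.csv`` with a ``# rate=<float>`` metadata line and a
``value`` column) plus ``<patient>/annotations.json``.

Time convention: all intervals are half-open ``[start_s, end_s)`` in seconds;
sample ``k`` of a channel at rate ``r`` covers ``[k/r, (k+1)/r)``.  Missing
samples are encoded as NaN and never imputed.

Note: :func:`mne.io.read_raw_edf` loads every EDF signal at the file's highest
sampling rate (lower-rate channels are upsampled by mne); native per-channel
rates are only preserved by the fixture dialect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel names, in the fixed order used throughout the package
CANONICAL_CHANNELS = ("NP", "THOR", "ABD", "HR", "PPG", "SPO2", "PCO2")

#: the five apnea/hypopnea kinds that constitute an adverse event
ADVERSE_KINDS = frozenset(
    {
        "central_apnea",
        "obstructive_apnea",
        "mixed_apnea",
        "central_hypopnea",
        "obstructive_hypopnea",
    }
)

#: every annotation kind accepted on input
EVENT_KINDS = frozenset(ADVERSE_KINDS | {"hypoxia", "movement"})


@dataclass
class Channel:
    """One physiological signal at its native sampling rate."""

    name: str
    samples: np.ndarray
    rate: float
    unit: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"channel {self.name}: samples must be 1-D")
        if not self.rate > 0:
            raise ValueError(f"channel {self.name}: rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Recording:
    """One patient's set of channels, keyed by canonical name."""

    patient_id: str
    channels: dict[str, Channel] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        if not self.channels:
            return 0.0
        return max(c.duration_s for c in self.channels.values())

    def __getitem__(self, name: str) -> Channel:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass(frozen=True)
class EventAnnotation:
    """A typed, timestamped half-open interval ``[start_s, end_s)``."""

    kind: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s}) for kind {self.kind}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _apply_channel_map(
    raw: dict[str, Channel], channel_map: dict[str, str] | None
) -> dict[str, Channel]:
    """Rename raw labels to canonical names; drop unmapped channels.

    Raw labels that already are canonical pass through unchanged, which makes
    canonicalization idempotent.
    """
    channel_map = dict(channel_map or {})
    out: dict[str, Channel] = {}
    for label, ch in raw.items():
        if label in channel_map:
            name = channel_map[label]
        elif label in CANONICAL_CHANNELS:
            name = label
        else:
            logger.warning("dropping unmapped channel %r", label)
            continue
        if name not in CANONICAL_CHANNELS:
            raise ValueError(f"channel map target {name!r} is not canonical")
        if name in out:
            raise ValueError(f"duplicate canonical channel {name!r}")
        ch.name = name
        out[name] = ch
    return out


def _check_mandatory(channels: dict[str, Channel]) -> None:
    missing = [c for c in CANONICAL_CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"missing channel {', '.join(missing)}")


def read_recording(
    path: str | Path,
    dialect: str = "fixture_csv",
    channel_map: dict[str, str] | None = None,
    require_all: bool = True,
) -> Recording:
    """Read one patient's recording.

    Parameters
    ----------
    path
        For ``fixture_csv``: the patient directory.  For ``edf``: the EDF file.
    dialect
        ``"fixture_csv"`` or ``"edf"``.
    channel_map
        Mapping from raw labels to canonical names.  Unmapped, non-canonical
        channels are dropped with a warning.
    require_all
        If true (default), raise if any of the seven canonical channels is
        absent after mapping.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if dialect == "fixture_csv":
        raw: dict[str, Channel] = {}
        for csv in sorted(path.glob("*.csv")):
            label = csv.stem
            with open(csv) as fh:
                header = fh.readline().strip()
            if not header.startswith("# rate="):
                raise IOError(f"{csv}: missing '# rate=' metadata line")
            rate = float(header.split("=", 1)[1])
            values = pd.read_csv(csv, skiprows=1, float_precision="round_trip")[
                "value"
            ].to_numpy(np.float64)
            raw[label] = Channel(label, values, rate)
        patient_id = path.name
    elif dialect == "edf":
        import mne

        rec = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        rate = float(rec.info["sfreq"])
        data = rec.get_data()
        raw = {
            name: Channel(name, data[i], rate) for i, name in enumerate(rec.ch_names)
        }
        patient_id = path.stem
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    channels = _apply_channel_map(raw, channel_map)
    if require_all:
        _check_mandatory(channels)
    return Recording(patient_id=patient_id, channels=channels)


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read an annotation track (JSON array or CSV with kind,start_s,end_s).

    Returns the events sorted by start time.  Rows with unknown kinds or
    non-positive-length intervals raise ``ValueError`` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        return []
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        rows = df.to_dict("records")
    out = []
    for i, row in enumerate(rows):
        try:
            out.append(
                EventAnnotation(
                    kind=str(row["kind"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"annotation row {i}: {exc}") from exc
    return sorted(out, key=lambda a: (a.start_s, a.end_s))


def write_fixture(
    recording: Recording,
    annotations: list[EventAnnotation],
    out_dir: str | Path,
) -> Path:
    """Write a recording + annotations in the fixture dialect.

    The dialect round-trips bit-exactly: samples are serialized with 17
    significant digits, which reproduces IEEE-754 doubles exactly.
    Returns the created patient directory.
    """
    out_dir = Path(out_dir)
    pdir = out_dir / recording.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    if not recording.channels:
        raise ValueError("recording has no channels")
    for name, ch in recording.channels.items():
        if len(ch.samples) == 0:
            raise ValueError(f"channel {name} has no samples")
        with open(pdir / f"{name}.csv", "w") as fh:
            fh.write(f"# rate={ch.rate!r}\nvalue\n")
            np.savetxt(fh, ch.samples, fmt="%.17g")
    payload = [
        {"kind": a.kind, "start_s": a.start_s, "end_s": a.end_s} for a in annotations
    ]
    (pdir / "annotations.json").write_text(json.dumps(payload, indent=1))
    return pdir
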