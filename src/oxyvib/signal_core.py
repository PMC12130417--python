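"""Domain types and delimited-text I/O for oxygenator vibration recordings.

A recording is a uniformly sampled triaxial accelerometer trace (in g) with
optional auxiliary channels on the same clock (oxygenator transmembrane
pressure, ECMO flow, hemodynamics).  A protocol timeline marks the phase
structure of an experiment (pump-speed sweep, anticoagulation reversal,
extraction timepoints) as labelled events on the recording clock.

All files are plain CSV: UTF-8, comma-separated, period decimal, one header
row.  Floats are written with 17 significant digits and parsed with
round-trip precision, so a write/read cycle is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AccelerometerRecording",
    "ProtocolTimeline",
    "CohortManifest",
    "ManifestEntry",
    "read_recording",
    "write_recording",
    "read_timeline",
    "write_timeline",
    "read_manifest",
    "write_manifest",
    "AUX_COLUMN_SUFFIX",
    "DEFAULT_SAMPLING_RATE_HZ",
    "IRREGULAR_SAMPLING_TOLERANCE",
]

#: Default sampling rate for fixtures and the simulator, samples/s.  The
#: smallest round rate whose Nyquist frequency clears the 375 Hz analysis
#: cutoff with margin.
DEFAULT_SAMPLING_RATE_HZ = 1000.0

#: Reject a time column if any inter-sample interval deviates from the
#: median interval by more than this relative amount.  The downstream DSP
#: assumes uniform sampling.
IRREGULAR_SAMPLING_TOLERANCE = 0.01

#: Unit suffix appended to an auxiliary channel's name to form its CSV
#: column header (``delta_p_oxy`` -> ``delta_p_oxy_mmHg``).  Channels not
#: listed here use their name verbatim as the column header.
AUX_COLUMN_SUFFIX: dict[str, str] = {
    "delta_p_oxy": "mmHg",
    "ecmo_flow": "lpm",
    "heart_rate": "bpm",
    "map": "mmHg",
    "cvp": "mmHg",
    "mpap": "mmHg",
    "spo2": "pct",
    "act": "s",
}

_REQUIRED_COLUMNS = ("time_s", "gx_g", "gy_g", "gz_g")

#: Well-known protocol event labels (free-text labels are also accepted).
KNOWN_EVENT_LABELS = frozenset(
    {
        "baseline_start",
        "pump_medium",
        "pump_high",
        "pre_reversal",
        "reversal",
        "t15",
        "t30",
        "t60",
        "end",
    }
)


def _aux_column_name(name: str) -> str:
    suffix = AUX_COLUMN_SUFFIX.get(name)
    return f"{name}_{suffix}" if suffix else name


def _aux_name_from_column(column: str) -> str:
    for name, suffix in AUX_COLUMN_SUFFIX.items():
        if column == f"{name}_{suffix}":
            return name
    return column


@dataclass
class AccelerometerRecording:
    """Uniformly sampled triaxial acceleration with optional aux channels.

    Parameters
    ----------
    sampling_rate_hz
        Sampling rate in samples per second; must exceed twice the analysis
        band's upper cutoff so the band is representable.
    gx, gy, gz
        Equal-length per-axis acceleration samples in units of g.
    aux_channels
        Optional named channels (pressure, flow, hemodynamics) sampled on
        the same clock, each the same length as the acceleration axes.
    subject_id
        Label identifying the animal/subject the recording belongs to.
    """

    sampling_rate_hz: float
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    aux_channels: dict[str, np.ndarray] = field(default_factory=dict)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.gx = np.asarray(self.gx, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        self.gz = np.asarray(self.gz, dtype=float)
        if not np.isfinite(self.sampling_rate_hz) or self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive and finite")
        n = self.gx.size
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        if self.gy.size != n or self.gz.size != n:
            raise ValueError(
                f"axis length mismatch: gx={n}, gy={self.gy.size}, gz={self.gz.size}"
            )
        converted = {}
        for name, values in self.aux_channels.items():
            values = np.asarray(values, dtype=float)
            if values.size != n:
                raise ValueError(
                    f"aux channel {name!r} has length {values.size}, expected {n}"
                )
            converted[name] = values
        self.aux_channels = converted

    @property
    def n_samples(self) -> int:
        return int(self.gx.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        """Sample timestamps, seconds from recording start (0-based)."""
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class ProtocolTimeline:
    """Ordered labelled events on the recording clock.

    Events split the recording into half-open phases ``[t_i, t_{i+1})``;
    the final phase runs to the end of the recording.
    """

    events: list[tuple[float, str]]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("timeline must contain at least one event")
        self.events = [(float(t), str(label)) for t, label in self.events]
        times = [t for t, _ in self.events]
        if any(t < 0 for t in times):
            raise ValueError("event times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("non-increasing event times")

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.events]

    def time_of(self, label: str) -> float:
        for t, lab in self.events:
            if lab == label:
                return t
        raise KeyError(f"no event labelled {label!r}")

    def has(self, label: str) -> bool:
        return any(lab == label for _, lab in self.events)

    def phases(self, duration_s: float | None = None) -> list[tuple[float, float, str]]:
        """Half-open intervals ``(start, end, label)``, one per event.

        The last phase is closed by ``duration_s`` when given, else left
        open (``end = inf``).
        """
        out = []
        for i, (t, label) in enumerate(self.events):
            if i + 1 < len(self.events):
                end = self.events[i + 1][0]
            else:
                end = float(duration_s) if duration_s is not None else float("inf")
            out.append((t, end, label))
        return out

    def validate_against(self, recording: AccelerometerRecording) -> None:
        last = self.events[-1][0]
        if last > recording.duration_s:
            raise ValueError(
                f"event at t={last} s lies beyond recording end "
                f"({recording.duration_s} s)"
            )


@dataclass
class ManifestEntry:
    subject_id: str
    recording_path: str
    timeline_path: str


@dataclass
class CohortManifest:
    """List of per-subject recording/timeline file pairs."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest must list at least one subject")
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Recording I/O


def infer_sampling_rate(time_s: np.ndarray) -> float:
    """Infer the sampling rate from a uniform time column.

    The rate is the reciprocal of the median inter-sample interval.  Raises
    if the grid is non-monotone or any interval deviates from the median by
    more than :data:`IRREGULAR_SAMPLING_TOLERANCE`.
    """
    time_s = np.asarray(time_s, dtype=float)
    if time_s.size < 2:
        raise ValueError("need at least two samples to infer a sampling rate")
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise ValueError("non-monotone time column")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > IRREGULAR_SAMPLING_TOLERANCE * med):
        raise ValueError(
            "irregular sampling: inter-sample interval deviates from the "
            f"median by more than {IRREGULAR_SAMPLING_TOLERANCE:.0%}"
        )
    return 1.0 / med


def read_recording(
    path: str | Path,
    sampling_rate_hz: float | None = None,
    subject_id: str | None = None,
) -> AccelerometerRecording:
    """Read a recording CSV (columns ``time_s, gx_g, gy_g, gz_g[, aux...]``).

    The sampling rate is inferred from the time column (median inter-sample
    interval) unless given explicitly.  Lines starting with ``#`` are
    metadata comments and are skipped.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if sampling_rate_hz is None:
        if len(df) < 2:
            raise ValueError(
                "cannot infer sampling rate from a single-row file; "
                "pass sampling_rate_hz explicitly"
            )
        sampling_rate_hz = infer_sampling_rate(df["time_s"].to_numpy())
    aux = {
        _aux_name_from_column(c): df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in _REQUIRED_COLUMNS
    }
    return AccelerometerRecording(
        sampling_rate_hz=float(sampling_rate_hz),
        gx=df["gx_g"].to_numpy(dtype=float),
        gy=df["gy_g"].to_numpy(dtype=float),
        gz=df["gz_g"].to_numpy(dtype=float),
        aux_channels=aux,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_recording(rec: AccelerometerRecording, path: str | Path) -> Path:
    """Write a recording as CSV with deterministic column order.

    Column order: ``time_s, gx_g, gy_g, gz_g`` then aux channels in sorted
    name order.  Floats are written at shortest round-trip precision.
    """
    path = Path(path)
    data: dict[str, np.ndarray] = {
        "time_s": rec.time_s,
        "gx_g": rec.gx,
        "gy_g": rec.gy,
        "gz_g": rec.gz,
    }
    for name in sorted(rec.aux_channels):
        data[_aux_column_name(name)] = rec.aux_channels[name]
    # %.17g guarantees binary round-trip of doubles through the text file
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Timeline I/O


def read_timeline(path: str | Path) -> ProtocolTimeline:
    """Read a two-column CSV ``time_s,label`` into a validated timeline."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"label": str}, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty timeline file: {path}")
    for col in ("time_s", "label"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    return ProtocolTimeline(
        events=list(zip(df["time_s"].astype(float), df["label"].astype(str)))
    )


def write_timeline(timeline: ProtocolTimeline, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(timeline.events, columns=["time_s", "label"]).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


# ---------------------------------------------------------------------------
# Manifest I/O (YAML)


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not doc or "subjects" not in doc:
        raise ValueError(f"manifest {path} lacks a 'subjects' list")
    entries = [
        ManifestEntry(
            subject_id=str(e["subject_id"]),
            recording_path=str(e["recording"]),
            timeline_path=str(e["timeline"]),
        )
        for e in doc["subjects"]
    ]
    return CohortManifest(entries=entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "n_subjects": manifest.n_subjects,
        "subjects": [
            {
                "subject_id": e.subject_id,
                "recording": e.recording_path,
                "timeline": e.timeline_path,
            }
            for e in manifest.entries
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path
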