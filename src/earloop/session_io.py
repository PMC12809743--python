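"""On-disk artifacts: EEG recordings, session logs, configs, model snapshots.

Formats are deliberately plain text so fixtures stay diffable:

* EEG: CSV with header ``time,left,right`` plus a ``<stem>.meta.json`` sidecar
  carrying the sampling rate, start time and event markers.
* Session logs: JSON lines, one record per song.
* Model snapshots: a single JSON document (full-precision floats, so a
  reloaded model reproduces predictions bit-identically).
* Run configuration: YAML.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import FormatError, StateError, ValidationError

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """Two-channel ear-canal EEG with event markers.

    ``samples`` is ``(2, n)`` in microvolts (arbitrary scale); channel order
    follows ``channel_names``. Event times are seconds relative to ``t0``.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, str] = ("left", "right")
    t0: float = 0.0
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[0] != 2:
            raise ValidationError(
                f"expected exactly 2 channels, got shape {self.samples.shape}"
            )
        if len(self.channel_names) != 2:
            raise ValidationError("channel_names must name exactly 2 channels")
        dur = self.duration
        for t, label in self.events:
            if not 0.0 <= t <= dur:
                raise ValidationError(
                    f"event {label!r} at {t} s outside recording [0, {dur}] s"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "EEGRecording":
        return EEGRecording(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            channel_names=self.channel_names,
            t0=self.t0,
            events=list(self.events),
        )


@dataclass
class SongRecord:
    song_id: str
    condition: str
    onset: float
    duration: float
    chill_press_times: list[float] = field(default_factory=list)
    vas_ratings: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for item, v in self.vas_ratings.items():
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"VAS rating {item}={v} outside [0, 100] for song {self.song_id}"
                )
        for t in self.chill_press_times:
            if not self.onset <= t <= self.onset + self.duration:
                raise ValidationError(
                    f"chill press at {t} s outside window of song {self.song_id}"
                )


@dataclass
class SessionLog:
    participant_id: str
    phase: str  # "recording" | "playlist"
    song_records: list[SongRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in ("recording", "playlist"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        for rec in self.song_records:
            rec.validate()


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the published defaults."""

    fs: float = 600.0
    filter_band: tuple[float, float] = (3.0, 40.0)
    filter_order: int = 4
    feature_band: tuple[float, float] = (4.0, 40.0)
    bin_width: float = 0.5
    epoch_len: float = 4.0
    overlap: float = 0.5
    noise_z: float = 2.5
    shape_stat: str = "skewness"  # offline default; "kurtosis" mirrors realtime text
    max_pcs: int = 150
    cv_model1_initial: int = 5
    cv_model1_retrain: int = 10
    cv_model2: int = 20
    test_frac: float = 0.1
    perm_n: int = 1000
    window_top: int = 72
    window_wide: int = 432
    baseline_window: tuple[int, int] = (3577, 3649)
    library_size: int = 7225
    song_len: float = 90.0
    playlist_len: int = 7
    smooth_k: int = 5
    embed_dim: int = 128
    embed_frames: int = 372
    agg_bin_len: float = 10.0
    sd_floor: float = 0.01
    clip_sd: float = 2.0
    feature_mode: str = "concat"  # "concat" | "mean"
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        for k, v in doc.items():
            if isinstance(v, tuple):
                doc[k] = list(v)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in doc:
                continue
            v = doc[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# EEG recordings
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_eeg_recording(recording: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    n = recording.n_samples
    times = recording.t0 + np.arange(n) / recording.fs
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", *recording.channel_names])
        for i in range(n):
            writer.writerow(
                [
                    repr(float(times[i])),
                    repr(float(recording.samples[0, i])),
                    repr(float(recording.samples[1, i])),
                ]
            )
    meta = {
        "fs": recording.fs,
        "t0": recording.t0,
        "channel_names": list(recording.channel_names),
        "events": [[float(t), str(lab)] for t, lab in recording.events],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_eeg_recording(path: str | Path, max_nan_run: int = 5) -> EEGRecording:
    """Read a ``time,left,right`` CSV plus its ``.meta.json`` sidecar.

    Rejects channels containing a run of more than ``max_nan_run``
    consecutive NaN samples.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable sidecar {sidecar}: {exc}") from exc
    fs = float(meta.get("fs", 0.0))
    if fs <= 0:
        raise ValidationError(f"sidecar fs must be positive, got {fs}")

    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[0] != "time":
            raise FormatError(f"{path}: expected header starting with 'time'")
        if len(header) != 3:
            raise ValidationError(
                f"{path}: expected 2 data channels, found {len(header) - 1}"
            )
        cols: list[list[float]] = [[], []]
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            try:
                cols[0].append(float(row[1]))
                cols[1].append(float(row[2]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc

    samples = np.array(cols, dtype=float)
    for ch in range(2):
        run = _longest_nan_run(samples[ch])
        if run > max_nan_run:
            raise ValidationError(
                f"channel {header[ch + 1]!r} has a NaN run of {run} samples "
                f"(limit {max_nan_run})"
            )
    return EEGRecording(
        samples=samples,
        fs=fs,
        channel_names=tuple(meta.get("channel_names", ("left", "right"))),
        t0=float(meta.get("t0", 0.0)),
        events=[(float(t), str(lab)) for t, lab in meta.get("events", [])],
    )


def _longest_nan_run(x: np.ndarray) -> int:
    isnan = np.isnan(x)
    if not isnan.any():
        return 0
    best = cur = 0
    for v in isnan:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# Session logs (JSON lines)
# ---------------------------------------------------------------------------


def write_session_log(log: SessionLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = {"participant_id": log.participant_id, "phase": log.phase}
        fh.write(json.dumps(header) + "\n")
        for rec in log.song_records:
            rec.validate()
            fh.write(json.dumps(dataclasses.asdict(rec)) + "\n")


def read_session_log(path: str | Path) -> SessionLog:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty session log")
    records: list[SongRecord] = []
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: line 1: {exc}") from exc
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            doc = json.loads(line)
            records.append(
                SongRecord(
                    song_id=doc["song_id"],
                    condition=doc["condition"],
                    onset=float(doc["onset"]),
                    duration=float(doc["duration"]),
                    chill_press_times=[float(t) for t in doc["chill_press_times"]],
                    vas_ratings={k: float(v) for k, v in doc["vas_ratings"].items()},
                )
            )
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return SessionLog(
        participant_id=header.get("participant_id", ""),
        phase=header.get("phase", "recording"),
        song_records=records,
    )


# ---------------------------------------------------------------------------
# Model snapshots
# ---------------------------------------------------------------------------


def save_model_snapshot(model, path: str | Path) -> None:
    """Serialize a fitted model to JSON; reload reproduces predictions exactly."""
    if not getattr(model, "fitted", False):
        raise StateError(f"cannot snapshot unfitted {type(model).__name__}")
    doc = {"kind": type(model).__name__, "payload": model.to_dict()}
    Path(path).write_text(json.dumps(doc))


def load_model_snapshot(path: str | Path):
    doc = json.loads(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "PleasureRegressor":
        from .model_acoustic import PleasureRegressor

        return PleasureRegressor.from_dict(doc["payload"])
    if kind == "EEGClassifier":
        from .model_eeg import EEGClassifier

        return EEGClassifier.from_dict(doc["payload"])
    raise FormatError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------


def write_ranking_csv(entries: Sequence[tuple[str, float]], path: str | Path) -> None:
    """Write ``rank,song_id,score`` rows, rank 1 first."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "song_id", "score"])
        for rank, (song_id, score) in enumerate(entries, start=1):
            writer.writerow([rank, song_id, repr(float(score))])


def read_ranking_csv(path: str | Path) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    with Path(path).open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["rank", "song_id", "score"]:
            raise FormatError(f"{path}: bad ranking header {header}")
        for row in reader:
            out.append((row[1], float(row[2])))
    return out


def json_default(obj):
    """Helper for dumping numpy scalars/arrays inside result documents."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
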