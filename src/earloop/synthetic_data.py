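"""Synthetic songs, participants and EEG with planted ground truth.

The generators exist so every downstream stage — featurization, both models,
ranking and the closed loop — can be exercised end to end without external
data. Song embeddings follow a low-rank latent factor model; a sparse planted
coefficient vector defines true pleasure; EEG is band-limited noise whose
per-band log power shifts between high- and low-pleasure states; chill counts
follow a Poisson whose log rate is linear in true pleasure, calibrated to the
published group means (self-selected: ~20.7 chills / ~86 VAS; other-selected:
~6.7 chills / ~57 VAS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .errors import ParameterError
from .session_io import EEGRecording, SessionLog, SongRecord

EMBED_DIM = 128

# Chill-rate calibration: log-linear through the two published group points.
CHILL_REF_PLEASURE = 86.1
CHILL_REF_RATE = 20.7
CHILL_SLOPE = math.log(20.7 / 6.7) / (86.1 - 57.1)

# Band definitions shared with the decoder.
EEG_BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 13.0), "beta": (14.0, 30.0), "gamma": (31.0, 40.0)}
BAND_BASE_AMP = {"theta": 1.0, "alpha": 1.2, "beta": 0.8, "gamma": 0.5}


@dataclass
class GroundTruth:
    """Planted parameters every simulated quantity derives from."""

    w_star: np.ndarray  # (128,) sparse
    active_set: np.ndarray
    pleasure_intercept: float
    pleasure_scale: float
    score_mean: float  # standardization of <mean embedding, w_star>
    score_sd: float
    eeg_effect: float  # per-band log-power shift between states
    seed: int

    def pleasure_from_score(self, score: np.ndarray) -> np.ndarray:
        if self.score_sd > 0:
            z = (score - self.score_mean) / self.score_sd
        else:
            z = np.zeros_like(score)
        return np.clip(self.pleasure_intercept + self.pleasure_scale * z, 0.0, 100.0)


@dataclass
class Song:
    song_id: str
    frame_embeddings: np.ndarray  # (frames, 128)
    base_pleasure: float  # library-level true pleasure before personal taste


@dataclass
class SongLibrary:
    songs: list[Song]

    def __len__(self) -> int:
        return len(self.songs)

    @property
    def song_ids(self) -> list[str]:
        return [s.song_id for s in self.songs]

    @property
    def base_pleasure(self) -> np.ndarray:
        return np.array([s.base_pleasure for s in self.songs])

    def frame_matrix(self, idx: int) -> np.ndarray:
        return self.songs[idx].frame_embeddings


def generate_song_library(
    n_songs: int,
    n_frames: int = 372,
    sparsity: int = 5,
    seed: int = 0,
    n_latent: int = 8,
    frame_noise: float = 0.3,
    eeg_effect: float = 1.0,
    pleasure_intercept: float = 50.0,
    pleasure_scale: float = 15.0,
) -> tuple[SongLibrary, GroundTruth]:
    """Low-rank frame embeddings plus a sparse planted pleasure map.

    True pleasure is a clipped affine transform of the standardized inner
    product between a song's mean embedding and ``w_star``. With
    ``sparsity=0`` every song's true pleasure equals the intercept.
    """
    if n_songs < 10:
        raise ParameterError(f"n_songs must be >= 10, got {n_songs}")
    if sparsity >= EMBED_DIM:
        raise ParameterError(f"sparsity must be < {EMBED_DIM}, got {sparsity}")
    rng = np.random.default_rng(seed)
    loadings = rng.normal(size=(n_latent, EMBED_DIM))
    w_star = np.zeros(EMBED_DIM)
    active = rng.choice(EMBED_DIM, size=sparsity, replace=False) if sparsity else np.array([], int)
    if sparsity:
        w_star[active] = rng.normal(size=sparsity) + np.sign(rng.normal(size=sparsity)) * 0.5

    factors = rng.normal(size=(n_songs, n_latent))
    base = factors @ loadings  # (n_songs, 128)
    songs: list[Song] = []
    mean_embs = np.empty((n_songs, EMBED_DIM))
    width = len(str(n_songs))
    for i in range(n_songs):
        frames = base[i] + frame_noise * rng.normal(size=(n_frames, EMBED_DIM))
        mean_embs[i] = frames.mean(axis=0)
        songs.append(Song(song_id=f"song{i:0{width}d}", frame_embeddings=frames, base_pleasure=0.0))

    score = mean_embs @ w_star
    truth = GroundTruth(
        w_star=w_star,
        active_set=np.sort(active),
        pleasure_intercept=pleasure_intercept,
        pleasure_scale=pleasure_scale,
        score_mean=float(score.mean()),
        score_sd=float(score.std()) if sparsity else 0.0,
        eeg_effect=eeg_effect,
        seed=seed,
    )
    pleasures = truth.pleasure_from_score(score)
    for song, p in zip(songs, pleasures):
        song.base_pleasure = float(p)
    return SongLibrary(songs=songs), truth


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------


def chill_rate(pleasure: np.ndarray, slope: float = CHILL_SLOPE) -> np.ndarray:
    """Expected chill count for a 90-s listen at the given pleasure level."""
    return CHILL_REF_RATE * np.exp(slope * (np.asarray(pleasure, dtype=float) - CHILL_REF_PLEASURE))


@dataclass
class SimulatedParticipant:
    participant_id: str
    personal_pleasure: np.ndarray  # (n_songs,) this listener's true pleasure
    self_idx: np.ndarray  # 3 library indices, top personal pleasure
    other_idx: np.ndarray  # 3 indices drawn from a donor participant's picks
    vas: dict[int, float]  # calibration song index -> rated VAS
    chills: dict[int, int]  # calibration song index -> chill count
    truth: GroundTruth
    seed: int

    @property
    def calibration_idx(self) -> np.ndarray:
        return np.concatenate([self.self_idx, self.other_idx])

    def calibration_labels(self) -> np.ndarray:
        return np.array([True] * 3 + [False] * 3)

    def high_state_probability(self, song_idx: int) -> float:
        p = self.personal_pleasure[song_idx]
        return float(1.0 / (1.0 + math.exp(-(p - 50.0) / 12.0)))


def _personal_pleasure(
    base: np.ndarray, rng: np.random.Generator, base_weight: float, taste_sd: float
) -> np.ndarray:
    own = rng.normal(scale=taste_sd, size=base.shape)
    return np.clip(50.0 + base_weight * (base - 50.0) + own, 0.0, 100.0)


def generate_participant(
    library: SongLibrary,
    truth: GroundTruth,
    seed: int = 0,
    base_weight: float = 0.35,
    taste_sd: float = 10.0,
    vas_noise_sd: float = 4.0,
    chill_slope: float = CHILL_SLOPE,
    participant_id: str | None = None,
) -> SimulatedParticipant:
    """One listener: personal taste, calibration picks, ratings, chills.

    Self-selected songs are the listener's top-3 by personal pleasure;
    other-selected songs are a simulated donor listener's top-3 (which share
    only the library-level component of taste). VAS = personal pleasure plus
    Gaussian noise; chills ~ Poisson with a log-linear rate in pleasure.
    """
    if len(library) < 6:
        raise ParameterError("library must contain at least 6 songs")
    rng = np.random.default_rng(seed)
    base = library.base_pleasure
    personal = _personal_pleasure(base, rng, base_weight, taste_sd)
    self_idx = np.argsort(personal)[::-1][:3]

    donor_personal = _personal_pleasure(base, rng, base_weight, taste_sd)
    donor_order = np.argsort(donor_personal)[::-1]
    other_idx = np.array([i for i in donor_order if i not in set(self_idx)][:3])

    vas: dict[int, float] = {}
    chills: dict[int, int] = {}
    for i in np.concatenate([self_idx, other_idx]):
        p = personal[i]
        vas[int(i)] = float(np.clip(p + rng.normal(scale=vas_noise_sd), 0.0, 100.0))
        chills[int(i)] = int(rng.poisson(chill_rate(p, slope=chill_slope)))
    return SimulatedParticipant(
        participant_id=participant_id or f"sim{seed:04d}",
        personal_pleasure=personal,
        self_idx=self_idx,
        other_idx=other_idx,
        vas=vas,
        chills=chills,
        truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfilt(sos, rng.normal(size=n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    spec = np.fft.rfft(rng.normal(size=n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_eeg(
    state: str,
    duration: float,
    truth: GroundTruth,
    artifact_rate: float = 0.0,
    seed: int = 0,
    fs: float = 600.0,
    epoch_len: float = 4.0,
    channel_coupling: float = 0.5,
    pink_amp: float = 0.5,
) -> EEGRecording:
    """Two-channel band-limited noise whose log band power encodes the state.

    Each channel sums theta/alpha/beta/gamma noise processes (per-band
    amplitude scaled by ``exp(±eeg_effect/4)`` so the between-state log-power
    shift equals ``eeg_effect``), a 1/f background, and optional transient
    high-amplitude artifacts at ``artifact_rate`` events per minute (logged
    as ``"artifact"`` events on the returned recording).
    """
    if state not in ("high", "low"):
        raise ParameterError(f"state must be 'high' or 'low', got {state!r}")
    if duration < epoch_len:
        raise ParameterError(f"duration {duration} s shorter than one epoch ({epoch_len} s)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    sign = 1.0 if state == "high" else -1.0
    gain = math.exp(sign * truth.eeg_effect / 4.0)

    common: dict[str, np.ndarray] = {
        name: _band_noise(rng, n, fs, band) for name, band in EEG_BANDS.items()
    }
    common["pink"] = _pink_noise(rng, n)
    channels = np.zeros((2, n))
    c = channel_coupling
    for ch in range(2):
        for name, band in EEG_BANDS.items():
            own = _band_noise(rng, n, fs, band)
            mixed = math.sqrt(1 - c**2) * own + c * common[name]
            channels[ch] += BAND_BASE_AMP[name] * gain * mixed
        own_pink = _pink_noise(rng, n)
        channels[ch] += pink_amp * (math.sqrt(1 - c**2) * own_pink + c * common["pink"])

    events: list[tuple[float, str]] = []
    if artifact_rate > 0:
        n_art = rng.poisson(artifact_rate * duration / 60.0)
        base_rms = channels.std()
        width = int(round(0.3 * fs))
        for _ in range(n_art):
            t0 = rng.uniform(0.0, duration - 0.3)
            s0 = int(t0 * fs)
            burst = 25.0 * base_rms * rng.normal(size=width) * scipy.signal.windows.hann(width)
            channels[:, s0 : s0 + width] += burst
            events.append((t0, "artifact"))
    return EEGRecording(samples=channels, fs=fs, events=sorted(events))


# ---------------------------------------------------------------------------
# Full study bundles
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    participant: SimulatedParticipant
    library: SongLibrary
    truth: GroundTruth
    calibration_recordings: list[tuple[int, bool, EEGRecording]]  # (song idx, label, rec)
    session_log: SessionLog


def simulate_listening(
    participant: SimulatedParticipant,
    library: SongLibrary,
    truth: GroundTruth,
    song_len: float = 90.0,
    artifact_rate: float = 0.0,
    seed: int = 0,
    fs: float = 600.0,
) -> StudyBundle:
    """Calibration phase: 6 recordings (high state for self-selected songs,
    low for other-selected) plus a session log with chill presses and VAS."""
    rng = np.random.default_rng(seed)
    recordings: list[tuple[int, bool, EEGRecording]] = []
    records: list[SongRecord] = []
    onset = 0.0
    for k, idx in enumerate(participant.calibration_idx):
        label = bool(participant.calibration_labels()[k])
        rec = generate_eeg(
            state="high" if label else "low",
            duration=song_len,
            truth=truth,
            artifact_rate=artifact_rate,
            seed=int(rng.integers(2**31)),
            fs=fs,
        )
        recordings.append((int(idx), label, rec))
        n_chills = participant.chills[int(idx)]
        press_times = sorted(onset + np.sort(rng.uniform(0.0, song_len, size=n_chills)))
        records.append(
            SongRecord(
                song_id=library.song_ids[int(idx)],
                condition="self" if label else "other",
                onset=onset,
                duration=song_len,
                chill_press_times=[float(t) for t in press_times],
                vas_ratings={"pleasure": participant.vas[int(idx)]},
            )
        )
        onset += song_len
    log = SessionLog(
        participant_id=participant.participant_id, phase="recording", song_records=records
    )
    return StudyBundle(
        participant=participant,
        library=library,
        truth=truth,
        calibration_recordings=recordings,
        session_log=log,
    )


def playback_state(
    participant: SimulatedParticipant, song_idx: int, rng: np.random.Generator
) -> str:
    """Draw the EEG state for a playlist song: P(high) rises with pleasure."""
    return "high" if rng.random() < participant.high_state_probability(song_idx) else "low"


# ---------------------------------------------------------------------------
# Study directory I/O (CLI `simulate` output)
# ---------------------------------------------------------------------------


def write_study(bundle: StudyBundle, directory) -> None:
    """Emit a complete study directory: truth JSON, per-song embedding CSVs,
    calibration EEG CSVs with sidecars, participant JSON and the session log."""
    import json
    from pathlib import Path

    from .session_io import write_eeg_recording, write_session_log

    directory = Path(directory)
    (directory / "embeddings").mkdir(parents=True, exist_ok=True)
    (directory / "calibration").mkdir(exist_ok=True)

    t = bundle.truth
    (directory / "truth.json").write_text(
        json.dumps(
            {
                "w_star": t.w_star.tolist(),
                "active_set": t.active_set.tolist(),
                "pleasure_intercept": t.pleasure_intercept,
                "pleasure_scale": t.pleasure_scale,
                "score_mean": t.score_mean,
                "score_sd": t.score_sd,
                "eeg_effect": t.eeg_effect,
                "seed": t.seed,
            }
        )
    )
    with (directory / "library.csv").open("w") as fh:
        fh.write("song_id,base_pleasure\n")
        for s in bundle.library.songs:
            fh.write(f"{s.song_id},{s.base_pleasure!r}\n")
    for s in bundle.library.songs:
        np.savetxt(directory / "embeddings" / f"{s.song_id}.csv", s.frame_embeddings, fmt="%.9g", delimiter=",")

    p = bundle.participant
    (directory / "participant.json").write_text(
        json.dumps(
            {
                "participant_id": p.participant_id,
                "seed": p.seed,
                "self_idx": p.self_idx.tolist(),
                "other_idx": p.other_idx.tolist(),
                "vas": {str(k): v for k, v in p.vas.items()},
                "chills": {str(k): v for k, v in p.chills.items()},
                "personal_pleasure": p.personal_pleasure.tolist(),
            }
        )
    )
    for k, (idx, label, rec) in enumerate(bundle.calibration_recordings):
        name = f"cal{k}_{bundle.library.song_ids[idx]}_{'self' if label else 'other'}.csv"
        write_eeg_recording(rec, directory / "calibration" / name)
    write_session_log(bundle.session_log, directory / "session_log.jsonl")


def load_study(directory) -> StudyBundle:
    """Inverse of :func:`write_study`."""
    import json
    from pathlib import Path

    from .session_io import read_eeg_recording, read_session_log

    directory = Path(directory)
    tdoc = json.loads((directory / "truth.json").read_text())
    truth = GroundTruth(
        w_star=np.array(tdoc["w_star"]),
        active_set=np.array(tdoc["active_set"], dtype=int),
        pleasure_intercept=tdoc["pleasure_intercept"],
        pleasure_scale=tdoc["pleasure_scale"],
        score_mean=tdoc["score_mean"],
        score_sd=tdoc["score_sd"],
        eeg_effect=tdoc["eeg_effect"],
        seed=tdoc["seed"],
    )
    songs = []
    with (directory / "library.csv").open() as fh:
        next(fh)
        for line in fh:
            song_id, base = line.strip().split(",")
            frames = np.loadtxt(directory / "embeddings" / f"{song_id}.csv", delimiter=",")
            songs.append(Song(song_id=song_id, frame_embeddings=frames, base_pleasure=float(base)))
    library = SongLibrary(songs=songs)

    pdoc = json.loads((directory / "participant.json").read_text())
    participant = SimulatedParticipant(
        participant_id=pdoc["participant_id"],
        personal_pleasure=np.array(pdoc["personal_pleasure"]),
        self_idx=np.array(pdoc["self_idx"], dtype=int),
        other_idx=np.array(pdoc["other_idx"], dtype=int),
        vas={int(k): v for k, v in pdoc["vas"].items()},
        chills={int(k): v for k, v in pdoc["chills"].items()},
        truth=truth,
        seed=pdoc["seed"],
    )
    recordings = []
    for path in sorted((directory / "calibration").glob("cal*.csv")):
        stem = path.stem  # cal<k>_<song_id>_<self|other>
        _, song_id, cond = stem.split("_", 2)
        idx = library.song_ids.index(song_id)
        recordings.append((idx, cond == "self", read_eeg_recording(path)))
    log = read_session_log(directory / "session_log.jsonl")
    return StudyBundle(
        participant=participant,
        library=library,
        truth=truth,
        calibration_recordings=recordings,
        session_log=log,
    )
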