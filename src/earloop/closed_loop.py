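"""Real-time decoding, VAS rescaling, regressor retraining, re-ranking.

Streaming decode: every second from t = 4 s the trailing 4-s window is
causally band-pass filtered (no component removal), featurized, standardized
with the calibration scaler, projected onto the stored PCA basis and decoded
to a pleasure probability; window noise metrics are z-scored against the
calibration statistics to set flags. After each non-baseline song of an
EEG-updated playlist, the song-mean decoded probability is rescaled to VAS
units via

    y' = (VAS_max - VAS_min) * ybar + VAS_min

standardized by the calibration VAS mean/SD, appended as a training point,
the acoustic regressor refit (10-fold CV), and the library re-ranked before
the next selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from . import synthetic_data
from .acoustic_features import (
    CalibrationScaler,
    build_calibration_matrix,
    normalize_and_clip_library,
    profile_song,
)
from .eeg_preprocessing import (
    FeatureScaler,
    NoiseStats,
    _design_bandpass,
    build_feature_set,
    compute_noise_metrics,
    compute_psd_matrix,
)
from .errors import (
    DegenerateInputError,
    NoSignalError,
    ParameterError,
    SchemaError,
    StateError,
)
from .model_acoustic import PleasureRegressor, fit_pleasure_regressor
from .model_eeg import EEGClassifier, build_training_set, fit_eeg_classifier
from .playlist_engine import (
    RankedLibrary,
    build_playlist_plan,
    rank_candidates,
    select_song,
    selection_window,
)
from .session_io import EEGRecording, RunConfig, SessionLog, SongRecord


@dataclass
class DecodedTrace:
    """One decoded probability per second, with flags and 5-point smoothing."""

    times: np.ndarray  # seconds (first at t = epoch_len)
    raw_probs: np.ndarray
    flags: np.ndarray  # True = window judged noisy
    smoothed: np.ndarray  # NaN before the first non-flagged value


@dataclass
class RetrainPoint:
    ybar: float
    vas_min: float
    vas_max: float
    y_prime: float
    y_std: float


def smooth_decoded(raw_probs: np.ndarray, flags: np.ndarray, k: int = 5) -> np.ndarray:
    """Moving average over the latest ``k`` non-flagged values.

    At each second: if at least ``k`` non-flagged values exist so far, the
    mean of the latest ``k``; otherwise the mean of all non-flagged so far;
    NaN until the first non-flagged value arrives.
    """
    raw_probs = np.asarray(raw_probs, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if raw_probs.shape != flags.shape:
        raise SchemaError("raw_probs and flags must be aligned")
    out = np.full(raw_probs.shape, np.nan)
    clean: list[float] = []
    for i, (p, bad) in enumerate(zip(raw_probs, flags)):
        if not bad:
            clean.append(float(p))
        if clean:
            window = clean[-k:] if len(clean) >= k else clean
            out[i] = float(np.mean(window))
    return out


def decode_stream(
    recording: EEGRecording,
    model2: EEGClassifier,
    feature_scaler: FeatureScaler,
    noise_stats: NoiseStats,
    cfg: RunConfig = RunConfig(),
) -> DecodedTrace:
    """Causal once-per-second decoding of a (simulated) stream."""
    if not model2.fitted:
        raise StateError("EEG classifier is not fitted")
    fs = recording.fs
    sos = _design_bandpass(*cfg.filter_band, cfg.filter_order, fs)
    filtered = scipy.signal.sosfilt(sos, recording.samples, axis=1)
    m = int(round(cfg.epoch_len * fs))
    last = int(np.floor(recording.duration))
    times = np.arange(int(cfg.epoch_len), last + 1, dtype=float)
    if times.size == 0:
        return DecodedTrace(
            times=times, raw_probs=np.empty(0), flags=np.empty(0, bool), smoothed=np.empty(0)
        )
    windows = np.stack(
        [filtered[:, int(t * fs) - m : int(t * fs)] for t in times]
    )  # (n, 2, m)
    raw = compute_psd_matrix(windows, fs, cfg.feature_band, cfg.bin_width)
    probs = model2.decode_features(feature_scaler.transform(raw))
    metrics = compute_noise_metrics(
        windows, fs, cfg.feature_band, cfg.bin_width, shape_stat=cfg.shape_stat
    )
    zs = noise_stats.composite_z(metrics)
    flags = np.logical_or.reduce([z > cfg.noise_z for z in zs.values()])
    smoothed = smooth_decoded(probs, flags, k=cfg.smooth_k)
    return DecodedTrace(times=times, raw_probs=probs, flags=flags, smoothed=smoothed)


def song_level_pleasure(trace: DecodedTrace) -> float:
    """Mean non-flagged raw decoded probability over the song."""
    keep = ~trace.flags
    if not keep.any():
        raise NoSignalError("every decoded second was flagged as noise")
    return float(trace.raw_probs[keep].mean())


def rescale_to_vas(ybar: float, vas_min: float, vas_max: float) -> float:
    """Exact affine map of a 0-1 decoded mean onto the calibration VAS range."""
    if vas_max <= vas_min:
        raise DegenerateInputError(
            f"degenerate calibration VAS range [{vas_min}, {vas_max}]"
        )
    if not 0.0 <= ybar <= 1.0:
        raise ParameterError(f"ybar must be in [0, 1], got {ybar}")
    return (vas_max - vas_min) * ybar + vas_min


def standardize_vas(y_prime: float, vas_mean: float, vas_sd: float) -> float:
    if vas_sd <= 0:
        raise DegenerateInputError("calibration VAS ratings have zero variance")
    return (y_prime - vas_mean) / vas_sd


def make_retrain_point(
    trace: DecodedTrace, vas_min: float, vas_max: float, vas_mean: float, vas_sd: float
) -> RetrainPoint:
    ybar = song_level_pleasure(trace)
    y_prime = rescale_to_vas(ybar, vas_min, vas_max)
    return RetrainPoint(
        ybar=ybar,
        vas_min=vas_min,
        vas_max=vas_max,
        y_prime=y_prime,
        y_std=standardize_vas(y_prime, vas_mean, vas_sd),
    )


def retrain_model1(
    cal_X: np.ndarray,
    cal_y: np.ndarray,
    new_X: np.ndarray,
    new_y: np.ndarray,
    cv_folds: int = 10,
    seed: int = 0,
) -> PleasureRegressor:
    """Refit on the six calibration rows plus the accumulated playlist rows."""
    new_X = np.atleast_2d(new_X)
    if new_X.shape[0] and new_X.shape[1] != cal_X.shape[1]:
        raise SchemaError("playlist-song features do not match the calibration mask")
    X = np.vstack([cal_X, new_X]) if new_X.shape[0] else cal_X
    y = np.concatenate([cal_y, np.atleast_1d(new_y)])
    return fit_pleasure_regressor(X, y, cv_folds=min(cv_folds, X.shape[0]), seed=seed)


# ---------------------------------------------------------------------------
# Calibration of a full participant state
# ---------------------------------------------------------------------------


@dataclass
class CalibrationState:
    """Everything the closed loop needs, fitted from the calibration phase."""

    model1: PleasureRegressor
    model2: EEGClassifier
    feature_scaler: FeatureScaler
    noise_stats: NoiseStats
    cal_scaler: CalibrationScaler
    cal_X: np.ndarray
    cal_y: np.ndarray
    vas_min: float
    vas_max: float
    vas_mean: float
    vas_sd: float
    self_vectors: np.ndarray  # clipped/normalized, for the similarity path
    pred_features: np.ndarray  # library, calibration z-scores (regressor input)
    sim_features: np.ndarray  # library, normalized + clipped
    song_ids: list[str]
    ranking: RankedLibrary


def calibrate_from_bundle(
    bundle: "synthetic_data.StudyBundle",
    cfg: RunConfig = RunConfig(),
    max_pcs: int | None = None,
    lambda_grid_size: int | None = None,
    cv_model2: int | None = None,
    seed: int = 0,
) -> CalibrationState:
    """Fit both models and the initial ranking from a calibration bundle."""
    library = bundle.library
    part = bundle.participant

    # --- EEG side ---
    labeled = [(rec, label) for _, label, rec in bundle.calibration_recordings]
    featset, metrics = build_feature_set(
        labeled,
        filter_band=cfg.filter_band,
        filter_order=cfg.filter_order,
        epoch_len=cfg.epoch_len,
        overlap=cfg.overlap,
        feature_band=cfg.feature_band,
        bin_width=cfg.bin_width,
        noise_z=cfg.noise_z,
        shape_stat=cfg.shape_stat,
        seed=seed,
    )
    noise_stats = NoiseStats.from_metrics(metrics)
    balanced = build_training_set(featset, max_pcs=max_pcs or cfg.max_pcs, seed=seed)
    grid = None
    if lambda_grid_size is not None:
        from .model_eeg import default_logistic_grid

        grid = default_logistic_grid(balanced.scores, balanced.labels.astype(float), lambda_grid_size)
    model2 = fit_eeg_classifier(
        balanced,
        cv_folds=cv_model2 or cfg.cv_model2,
        lambda_grid=grid,
        test_frac=cfg.test_frac,
        seed=seed,
    )

    # --- acoustic side ---
    profiles = [
        profile_song(
            library.song_ids[i],
            library.frame_matrix(i),
            bin_len=cfg.agg_bin_len,
            excerpt_len=cfg.song_len,
            mode=cfg.feature_mode,
        )
        for i in part.calibration_idx
    ]
    ratings = [part.vas[int(i)] for i in part.calibration_idx]
    cal_X, cal_y, cal_scaler = build_calibration_matrix(profiles, ratings)
    model1 = fit_pleasure_regressor(cal_X, cal_y, cv_folds=cfg.cv_model1_initial, seed=seed)

    lib_vectors = np.stack(
        [
            profile_song(
                library.song_ids[i],
                library.frame_matrix(i),
                bin_len=cfg.agg_bin_len,
                excerpt_len=cfg.song_len,
                mode=cfg.feature_mode,
            ).feature_vector
            for i in range(len(library))
        ]
    )
    pred_features = cal_scaler.transform(lib_vectors)
    sim_features = normalize_and_clip_library(lib_vectors, cal_scaler, clip_sd=cfg.clip_sd)
    self_vectors = sim_features[part.self_idx]

    ranking = rank_candidates(
        model1, pred_features, sim_features, self_vectors, library.song_ids
    )
    ratings_arr = np.asarray(ratings, dtype=float)
    return CalibrationState(
        model1=model1,
        model2=model2,
        feature_scaler=featset.scaler,
        noise_stats=noise_stats,
        cal_scaler=cal_scaler,
        cal_X=cal_X,
        cal_y=cal_y,
        vas_min=float(ratings_arr.min()),
        vas_max=float(ratings_arr.max()),
        vas_mean=float(ratings_arr.mean()),
        vas_sd=float(ratings_arr.std()),
        self_vectors=self_vectors,
        pred_features=pred_features,
        sim_features=sim_features,
        song_ids=list(library.song_ids),
        ranking=ranking,
    )


# ---------------------------------------------------------------------------
# Session loop
# ---------------------------------------------------------------------------


@dataclass
class SlotResult:
    slot: int
    song_id: str
    window: tuple[int, int]
    true_pleasure: float
    decoded_mean: float | None
    y_std: float | None
    n_flagged: int
    n_windows: int
    retrained: bool


@dataclass
class SessionResult:
    condition: str
    slots: list[SlotResult]
    decoded_means: list[float | None]
    baseline_corrected: list[float | None]
    retrain_events: int
    session_log: SessionLog
    traces: list[DecodedTrace] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "retrain_events": self.retrain_events,
            "slots": [
                {
                    "slot": s.slot,
                    "song_id": s.song_id,
                    "window": list(s.window),
                    "true_pleasure": s.true_pleasure,
                    "decoded_mean": s.decoded_mean,
                    "y_std": s.y_std,
                    "n_flagged": s.n_flagged,
                    "n_windows": s.n_windows,
                    "retrained": s.retrained,
                }
                for s in self.slots
            ],
            "decoded_means": self.decoded_means,
            "baseline_corrected": self.baseline_corrected,
        }


def run_session(
    bundle: "synthetic_data.StudyBundle",
    condition: str,
    state: CalibrationState,
    cfg: RunConfig = RunConfig(),
    seed: int = 0,
    song_len: float | None = None,
    artifact_rate: float = 0.0,
    retrain_mode: str = "accumulate",
) -> SessionResult:
    """Simulate one playlist session of 7 songs under the given condition.

    For EEG conditions, after each non-baseline song the decoded pleasure is
    rescaled and appended (``retrain_mode="accumulate"``; ``"latest"`` keeps
    only the most recent point), the regressor refit and the library
    re-ranked before the next selection. Songs whose every decoded second is
    flagged contribute no retraining point but the session continues.
    """
    if retrain_mode not in ("accumulate", "latest"):
        raise ParameterError(f"unknown retrain_mode {retrain_mode!r}")
    part = bundle.participant
    library = bundle.library
    song_len = song_len if song_len is not None else cfg.song_len
    idx_of = {sid: i for i, sid in enumerate(library.song_ids)}
    eeg_updates = condition in ("AugEEG", "DimEEG")

    plan = build_playlist_plan(condition, state.ranking, seed=seed)
    rng = np.random.default_rng(seed + 1)
    ranking = state.ranking
    model1 = state.model1
    played: set[str] = {s for s in plan.song_ids if s is not None}
    new_X: list[np.ndarray] = []
    new_y: list[float] = []

    slots: list[SlotResult] = []
    records: list[SongRecord] = []
    traces: list[DecodedTrace] = []
    retrain_events = 0
    onset = 0.0
    for slot in range(1, 8):
        window = plan.windows[slot - 1]
        song_id = plan.song_ids[slot - 1]
        if song_id is None:
            song_id = select_song(ranking, window, played, rng)
            played.add(song_id)
        i = idx_of[song_id]

        rec = synthetic_data.generate_eeg(
            state=synthetic_data.playback_state(part, i, rng),
            duration=song_len,
            truth=bundle.truth,
            artifact_rate=artifact_rate,
            seed=int(rng.integers(2**31)),
            fs=cfg.fs,
        )
        trace = decode_stream(rec, state.model2, state.feature_scaler, state.noise_stats, cfg)
        traces.append(trace)

        n_chills = int(rng.poisson(synthetic_data.chill_rate(part.personal_pleasure[i])))
        press = sorted(onset + rng.uniform(0.0, song_len, size=n_chills))
        records.append(
            SongRecord(
                song_id=song_id,
                condition=condition,
                onset=onset,
                duration=song_len,
                chill_press_times=[float(t) for t in press],
                vas_ratings={},
            )
        )

        decoded_mean: float | None
        try:
            decoded_mean = song_level_pleasure(trace)
        except NoSignalError:
            decoded_mean = None

        retrained = False
        y_std = None
        if eeg_updates and slot >= 2 and decoded_mean is not None:
            point = make_retrain_point(
                trace, state.vas_min, state.vas_max, state.vas_mean, state.vas_sd
            )
            y_std = point.y_std
            x_new = state.pred_features[i]
            if retrain_mode == "accumulate":
                new_X.append(x_new)
                new_y.append(point.y_std)
            else:
                new_X, new_y = [x_new], [point.y_std]
            model1 = retrain_model1(
                state.cal_X,
                state.cal_y,
                np.stack(new_X),
                np.array(new_y),
                cv_folds=cfg.cv_model1_retrain,
                seed=seed,
            )
            ranking = rank_candidates(
                model1, state.pred_features, state.sim_features, state.self_vectors, state.song_ids
            )
            retrained = True
            retrain_events += 1

        slots.append(
            SlotResult(
                slot=slot,
                song_id=song_id,
                window=window,
                true_pleasure=float(part.personal_pleasure[i]),
                decoded_mean=decoded_mean,
                y_std=y_std,
                n_flagged=int(trace.flags.sum()),
                n_windows=int(len(trace.flags)),
                retrained=retrained,
            )
        )
        onset += song_len

    decoded_means = [s.decoded_mean for s in slots]
    baseline = decoded_means[0]
    corrected = [
        None if (m is None or baseline is None) else m - baseline for m in decoded_means
    ]
    log = SessionLog(
        participant_id=part.participant_id, phase="playlist", song_records=records
    )
    return SessionResult(
        condition=condition,
        slots=slots,
        decoded_means=decoded_means,
        baseline_corrected=corrected,
        retrain_events=retrain_events,
        session_log=log,
        traces=traces,
    )
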