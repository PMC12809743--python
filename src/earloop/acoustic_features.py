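"""Frame-level 128-d audio embeddings -> standardized per-song feature vectors.

Frames are averaged into 10-s bins (9 bins for a 90-s excerpt). A song's
feature vector is either the flattened 9 x 128 bin means ("concat", default)
or the 128-d grand mean ("mean"). Calibration fits a per-dimension z-scaler
across the six songs, keeping only dimensions with a finite mean and SD
greater than 0.01; the same retained-dimension mask is applied everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    CoverageError,
    DegenerateInputError,
    ParameterError,
    SchemaError,
)

SD_FLOOR = 0.01


@dataclass
class AcousticProfile:
    """One song's embeddings plus aggregates used by the regressor/ranker."""

    song_id: str
    frame_matrix: np.ndarray  # (frames, 128)
    frame_times: np.ndarray  # (frames,) frame midpoints in seconds
    means_10s: np.ndarray  # (bins, 128)
    feature_vector: np.ndarray  # 1152 (concat) or 128 (mean)
    mode: str = "concat"


@dataclass
class CalibrationScaler:
    """Per-dimension mean/SD over the six calibration songs + retained mask."""

    mean: np.ndarray  # over raw (unmasked) dimensions
    sd: np.ndarray
    mask: np.ndarray  # bool, True = retained
    sd_floor: float = SD_FLOOR

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        if vectors.shape[1] != self.mask.shape[0]:
            raise SchemaError(
                f"vector width {vectors.shape[1]} != scaler width {self.mask.shape[0]}"
            )
        z = (vectors[:, self.mask] - self.mean[self.mask]) / self.sd[self.mask]
        return z

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "mask": self.mask.astype(int).tolist(),
            "sd_floor": self.sd_floor,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CalibrationScaler":
        return cls(
            mean=np.array(doc["mean"], dtype=float),
            sd=np.array(doc["sd"], dtype=float),
            mask=np.array(doc["mask"], dtype=bool),
            sd_floor=doc["sd_floor"],
        )


def frame_average(
    frame_matrix: np.ndarray,
    frame_times: np.ndarray | None = None,
    bin_len: float = 10.0,
    excerpt_len: float = 90.0,
) -> np.ndarray:
    """Average frames into consecutive ``bin_len``-second bins.

    Frames are assigned to half-open bins ``[k*bin_len, (k+1)*bin_len)`` by
    their midpoint time. When ``frame_times`` is omitted, frames are assumed
    uniform over the excerpt. An empty bin raises :class:`CoverageError`.
    """
    frame_matrix = np.asarray(frame_matrix, dtype=float)
    n_frames = frame_matrix.shape[0]
    if n_frames == 0:
        raise CoverageError("no frames supplied")
    if frame_times is None:
        frame_times = (np.arange(n_frames) + 0.5) * excerpt_len / n_frames
    frame_times = np.asarray(frame_times, dtype=float)
    n_bins = int(round(excerpt_len / bin_len))
    idx = np.floor(frame_times / bin_len).astype(int)
    out = np.empty((n_bins, frame_matrix.shape[1]))
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            raise CoverageError(f"no frames fall in bin {b} ([{b * bin_len}, {(b + 1) * bin_len}) s)")
        out[b] = frame_matrix[sel].mean(axis=0)
    return out


def profile_song(
    song_id: str,
    frame_matrix: np.ndarray,
    frame_times: np.ndarray | None = None,
    bin_len: float = 10.0,
    excerpt_len: float = 90.0,
    mode: str = "concat",
) -> AcousticProfile:
    if mode not in ("concat", "mean"):
        raise ParameterError(f"unknown feature mode {mode!r}")
    frame_matrix = np.asarray(frame_matrix, dtype=float)
    n_frames = frame_matrix.shape[0]
    if frame_times is None:
        frame_times = (np.arange(n_frames) + 0.5) * excerpt_len / n_frames
    means = frame_average(frame_matrix, frame_times, bin_len, excerpt_len)
    vec = means.reshape(-1) if mode == "concat" else frame_matrix.mean(axis=0)
    return AcousticProfile(
        song_id=song_id,
        frame_matrix=frame_matrix,
        frame_times=np.asarray(frame_times, dtype=float),
        means_10s=means,
        feature_vector=vec,
        mode=mode,
    )


def build_calibration_matrix(
    profiles: Sequence[AcousticProfile],
    ratings: Sequence[float],
    strict_design: bool = True,
) -> tuple[np.ndarray, np.ndarray, CalibrationScaler]:
    """Z-score song feature vectors and VAS ratings across the calibration set.

    Population-SD convention throughout. Dimensions with a non-finite mean or
    an SD of at most 0.01 are dropped; the resulting mask is stored in the
    returned scaler and must be reused for candidates and retraining points.
    """
    if strict_design and len(profiles) != 6:
        raise ParameterError(
            f"calibration design expects 6 songs (3 self + 3 other), got {len(profiles)}"
        )
    if len(profiles) != len(ratings):
        raise ParameterError("one rating per profile required")
    V = np.stack([p.feature_vector for p in profiles])  # (n_songs, d)
    mean = V.mean(axis=0)
    sd = V.std(axis=0)
    mask = np.isfinite(mean) & (sd > SD_FLOOR)
    if not mask.any():
        raise DegenerateInputError("no embedding dimension passed the retention filter")
    scaler = CalibrationScaler(mean=mean, sd=sd, mask=mask)
    X = scaler.transform(V)
    y_raw = np.asarray(ratings, dtype=float)
    y_sd = y_raw.std()
    if y_sd == 0:
        raise DegenerateInputError("all calibration ratings identical; response has zero variance")
    y = (y_raw - y_raw.mean()) / y_sd
    return X, y, scaler


def normalize_and_clip_library(
    vectors: np.ndarray,
    scaler: CalibrationScaler,
    clip_sd: float = 2.0,
    stats: str = "library",
) -> np.ndarray:
    """Standardize candidate feature vectors and clip at ±``clip_sd``.

    ``stats="library"`` z-scores with the library's own per-dimension
    statistics (the default for the similarity/clip path);
    ``stats="calibration"`` reuses the calibration scaler's statistics.
    The calibration retained-dimension mask applies in both cases.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[1] != scaler.mask.shape[0]:
        raise SchemaError(
            f"library width {vectors.shape[1]} != calibration width {scaler.mask.shape[0]}"
        )
    if stats == "calibration":
        z = scaler.transform(vectors)
    elif stats == "library":
        sub = vectors[:, scaler.mask]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        z = (sub - mean) / sd
    else:
        raise ParameterError(f"unknown stats source {stats!r}")
    return np.clip(z, -clip_sd, clip_sd)


def similarity_to_self(
    candidate_vector: np.ndarray, self_vectors: np.ndarray
) -> tuple[np.ndarray, float]:
    """Pearson r between a candidate and each self-selected song's vector.

    Returns the per-song correlations and their mean.
    """
    candidate_vector = np.asarray(candidate_vector, dtype=float)
    self_vectors = np.atleast_2d(np.asarray(self_vectors, dtype=float))
    if self_vectors.shape[1] != candidate_vector.shape[0]:
        raise SchemaError("candidate and self-song vectors have different widths")
    c = candidate_vector - candidate_vector.mean()
    c_norm = np.sqrt((c**2).sum())
    if c_norm == 0:
        raise DegenerateInputError("candidate vector has zero variance; correlation undefined")
    rs = np.empty(self_vectors.shape[0])
    for i, s in enumerate(self_vectors):
        s0 = s - s.mean()
        s_norm = np.sqrt((s0**2).sum())
        if s_norm == 0:
            raise DegenerateInputError(
                f"self-selected vector {i} has zero variance; correlation undefined"
            )
        rs[i] = float(c @ s0) / (c_norm * s_norm)
    return rs, float(rs.mean())
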