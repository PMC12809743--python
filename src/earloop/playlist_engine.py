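"""Composite ranking of the candidate library and per-condition song selection.

The composite score z-scores the regressor's predicted pleasure across the
library and adds the z-scored mean correlation to the three self-selected
songs; candidates are ranked descending with deterministic song-id
tie-breaking. Selection windows at the published library size of 7,225 are
top/bottom 72 (EEG conditions), top/bottom 432 (no-EEG conditions) and the
central baseline band 3,577-3,649; other sizes scale by the same fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustic_features import similarity_to_self
from .errors import ExhaustionError, ParameterError, StateError
from .model_acoustic import PleasureRegressor, predict_pleasure

CONDITIONS = ("AugEEG", "AugNoEEG", "DimEEG", "DimNoEEG")


@dataclass
class RankedLibrary:
    song_ids: list[str]  # rank order: index 0 = rank 1 = highest score
    scores: np.ndarray
    predicted_z: np.ndarray
    similarity_z: np.ndarray
    library_size: int

    def rank_of(self, song_id: str) -> int:
        return self.song_ids.index(song_id) + 1


@dataclass
class PlaylistPlan:
    condition: str
    windows: list[tuple[int, int]]  # per slot, 1-based inclusive rank windows
    song_ids: list[str | None]  # None = deferred (resolved by the closed loop)
    seed: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def rank_candidates(
    model1: PleasureRegressor,
    prediction_features: np.ndarray,
    similarity_features: np.ndarray,
    self_vectors: np.ndarray,
    song_ids: list[str],
    zscore_predictions: bool = True,
) -> RankedLibrary:
    """Composite = z(predicted pleasure) + z(mean self-similarity), descending.

    ``prediction_features`` feed the regressor (calibration z-scores);
    ``similarity_features`` are the normalized/clipped vectors used for the
    correlation path. Ties break by ascending song id.
    """
    n = len(song_ids)
    if prediction_features.shape[0] != n or similarity_features.shape[0] != n:
        raise ParameterError("feature row counts must match the song-id list")
    pred = predict_pleasure(model1, prediction_features)
    pred_z = _zscore(pred) if zscore_predictions else pred
    sims = np.empty(n)
    for i in range(n):
        _, sims[i] = similarity_to_self(similarity_features[i], self_vectors)
    sim_z = _zscore(sims)
    score = pred_z + sim_z
    order = sorted(range(n), key=lambda i: (-score[i], song_ids[i]))
    return RankedLibrary(
        song_ids=[song_ids[i] for i in order],
        scores=score[order],
        predicted_z=pred_z[order],
        similarity_z=sim_z[order],
        library_size=n,
    )


def window_widths(library_size: int) -> tuple[int, int, int]:
    """(narrow, wide, baseline) widths: 1% (floored), 6x narrow, narrow + 1.

    For small synthetic libraries the narrow window is floored at 8 so six
    distinct non-baseline picks always fit; at the published size of 7,225
    the widths are exactly 72 / 432 / 73.
    """
    narrow = max(8, library_size // 100)
    wide = 6 * narrow
    if library_size < wide + narrow + 1:
        raise ParameterError(f"library of {library_size} songs is too small to window")
    return narrow, wide, narrow + 1


def selection_window(
    condition: str, slot: int, library_size: int
) -> tuple[int, int]:
    """1-based inclusive rank window for a playlist slot.

    Slot 1 is always the central baseline band. For 7,225 songs this yields
    the published windows exactly: [1, 72] / [1, 432] for the augmenting
    conditions, [7154, 7225] / [6794, 7225] for the diminishing ones, and
    baseline [3577, 3649].
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}")
    if not 1 <= slot <= 7:
        raise ParameterError(f"slot must be in 1..7, got {slot}")
    narrow, wide, base_width = window_widths(library_size)
    if library_size < wide:
        raise ParameterError("library smaller than the widest selection window")
    if slot == 1:
        center = (library_size + 1) // 2
        lo = center - base_width // 2
        return lo, lo + base_width - 1
    width = narrow if condition.endswith("EEG") and "No" not in condition else wide
    if condition.startswith("Aug"):
        return 1, width
    return library_size - width + 1, library_size


def select_song(
    ranking: RankedLibrary,
    window: tuple[int, int],
    already_played: set[str] | None = None,
    seed: int | np.random.Generator = 0,
) -> str:
    """Uniform seeded draw from the rank window, excluding played songs."""
    already_played = already_played or set()
    lo, hi = window
    pool = [s for s in ranking.song_ids[lo - 1 : hi] if s not in already_played]
    if not pool:
        raise ExhaustionError(f"window [{lo}, {hi}] has no unplayed songs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return pool[int(rng.integers(len(pool)))]


def build_playlist_plan(condition: str, ranking: RankedLibrary, seed: int = 0) -> PlaylistPlan:
    """Seven slots: slot 1 drawn from the baseline band; for no-EEG conditions
    slots 2-7 are drawn up-front from the fixed ranking; for EEG conditions
    they stay deferred until the closed loop resolves them after each retrain."""
    rng = np.random.default_rng(seed)
    windows = [selection_window(condition, s, ranking.library_size) for s in range(1, 8)]
    played: set[str] = set()
    song_ids: list[str | None] = []
    baseline = select_song(ranking, windows[0], played, rng)
    song_ids.append(baseline)
    played.add(baseline)
    deferred = "No" not in condition  # AugEEG / DimEEG resolve slots live
    for s in range(1, 7):
        if deferred:
            song_ids.append(None)
        else:
            pick = select_song(ranking, windows[s], played, rng)
            song_ids.append(pick)
            played.add(pick)
    return PlaylistPlan(condition=condition, windows=windows, song_ids=song_ids, seed=seed)
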