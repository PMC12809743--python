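# earloop

Closed-loop in-ear EEG music pleasure pipeline. `earloop` decodes momentary
musical pleasure from two-channel ear-canal EEG, predicts pleasure from
128-dimensional audio embeddings, ranks a candidate-song library by a
composite of predicted pleasure and acoustic similarity to a listener's
favorite songs, and runs the closed loop in which EEG-decoded pleasure
retrains the acoustic model and re-ranks songs after every playlist track.
Everything is exercisable end to end on bundled synthetic data with planted
ground truth.

## Pipeline

1. **Calibration** — the listener hears 3 self-selected (high-pleasure) and
   3 other-selected (low-pleasure) 90-s excerpts, pressing a key at every
   chill and rating each song on a 0–100 VAS.
2. **EEG decoder** (`model_eeg`) — raw EEG is band-passed (4th-order
   Butterworth, 3–40 Hz), blind-separated into two components with the
   larger-RMS component removed, cut into 4-s epochs (50% overlap), and
   featurized as Welch band power in 73 half-Hz bins from 4–40 Hz for the
   left, right and difference derivations (219 features). Noisy epochs
   (RMS / max-gradient / skewness z > 2.5) are flagged; features are
   standardized, projected onto ≤150 principal components, classes balanced,
   and a logistic LASSO fit on a 90/10 split with 20-fold CV, validated by
   confusion matrix / ROC-AUC, a 1,000-shuffle permutation test, and weight
   back-projection into frequency × derivation space.
3. **Acoustic regressor** (`model_acoustic`) — per-song frame embeddings are
   averaged into 10-s bins (9 × 128 per 90-s excerpt), z-scored across the
   six calibration songs (dimensions with NaN means or SD ≤ 0.01 dropped),
   and a linear LASSO maps them to z-scored VAS (λ by 5-fold CV).
4. **Ranking & playlists** (`playlist_engine`) — candidates are normalized,
   clipped at ±2 SD, scored by z(predicted pleasure) + z(mean correlation to
   the self-selected songs), and ranked. Four conditions select from the
   top 1% (AugEEG), top 6% (AugNoEEG), bottom 1% (DimEEG) or bottom 6%
   (DimNoEEG); every playlist opens with a mid-ranking baseline song
   (positions 3,577–3,649 at the published 7,225-song library).
5. **Closed loop** (`closed_loop`) — during EEG-updated playlists, the
   trailing 4-s window is causally decoded once per second (5-point
   flag-aware smoothing), the song-mean decoded probability is rescaled to
   VAS units (`y' = (VASmax − VASmin)·ȳ + VASmin`), standardized, appended
   as a training point, and the regressor refit (10-fold CV) and library
   re-ranked before the next selection.
6. **Reporting** (`evaluation_report`) — chill counts (slots 2–7), inclusion
   checks (≥3 more chills and higher mean VAS for self-selected songs), and
   baseline-corrected decoded-pleasure summaries.

`synthetic_data` generates the whole study — low-rank frame embeddings with
a sparse planted pleasure map, participants whose chill counts and VAS
ratings reproduce the published group statistics, and band-limited-noise EEG
whose per-band log power shifts with the pleasure state.

## CLI

```sh
earloop simulate --out study/ --n-songs 150 --seed 1   # synthetic study dir
earloop preprocess --study study/ --out features/      # 219-dim epoch features
earloop train-acoustic --study study/ --out model1.json
earloop train-eeg --study study/ --out model2.json
earloop validate-eeg --study study/ --out validation/ --n-perm 100
earloop rank --study study/ --out ranking.csv
earloop plan --study study/ --condition AugNoEEG --out plan.json
earloop run-loop --study study/ --condition AugEEG --out result.json
earloop report --result result.json --out report/
```

All artifacts are plain text: EEG as `time,left,right` CSV with a
`.meta.json` sidecar, session logs as JSON lines, rankings as CSV, model
snapshots as full-precision JSON (reload reproduces predictions
bit-identically), configuration as YAML (`earloop.session_io.RunConfig`).

## Layout

```
src/earloop/
  session_io.py        on-disk formats, RunConfig, model snapshots
  synthetic_data.py    planted-truth song/participant/EEG generators
  eeg_preprocessing.py filter, separation, epoching, PSD, flags, scaling
  acoustic_features.py frame averaging, calibration scaler, similarity
  model_acoustic.py    linear LASSO pleasure regressor (CV over a λ path)
  model_eeg.py         PCA + logistic LASSO decoder, permutation test,
                       weight back-projection
  playlist_engine.py   composite ranking, selection windows, playlist plans
  closed_loop.py       streaming decode, VAS rescaling, retrain/re-rank loop
  evaluation_report.py chill counts, inclusion checks, baseline correction
  cli.py               click command group (see above)
```
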