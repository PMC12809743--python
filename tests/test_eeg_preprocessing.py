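import numpy as np
import pytest
import scipy.signal

from earloop.eeg_preprocessing import (
    NoiseStats,
    bandpass_filter,
    bin_centers,
    compute_noise_metrics,
    compute_psd_features,
    compute_psd_matrix,
    epoch_signal,
    flag_noisy_epochs,
    remove_artifact_component,
    standardize_features,
)
from earloop.errors import (
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from earloop.session_io import EEGRecording

FS = 600.0


def _rec(samples):
    return EEGRecording(samples=np.asarray(samples, dtype=float), fs=FS)


def _sine(freq, duration=10.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


# --- bandpass filter ---


def test_passband_preserves_10hz():
    x = _sine(10.0)
    out = bandpass_filter(_rec(np.stack([x, x])), 3, 40).samples[0]
    mid = slice(int(2 * FS), int(8 * FS))  # avoid edges
    ratio = np.abs(out[mid]).max() / np.abs(x[mid]).max()
    assert abs(ratio - 1.0) < 0.05


def test_stopband_attenuates_1hz():
    # Oracle: squared magnitude (forward-backward) of the designed filter at 1 Hz.
    sos = scipy.signal.butter(4, [3, 40], btype="bandpass", fs=FS, output="sos")
    _, h = scipy.signal.sosfreqz(sos, worN=[1.0], fs=FS)
    expected_gain = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
    assert expected_gain < 0.1  # the published band attenuates 1 Hz by > 90%

    x = _sine(1.0, duration=30.0)
    out = bandpass_filter(_rec(np.stack([x, x])), 3, 40).samples[0]
    mid = slice(int(10 * FS), int(20 * FS))
    measured = np.abs(out[mid]).max() / np.abs(x[mid]).max()
    assert measured < 0.1
    assert measured == pytest.approx(expected_gain, rel=0.25)


def test_dc_offset_removed():
    x = 100.0 + _sine(10.0)
    out = bandpass_filter(_rec(np.stack([x, x])), 3, 40).samples[0]
    assert abs(out[int(2 * FS) :].mean()) < 0.5


def test_high_cutoff_above_nyquist_rejected():
    with pytest.raises(ParameterError):
        bandpass_filter(_rec(np.zeros((2, 600))), 3, 400)


def test_realtime_mode_is_causal():
    x = np.zeros(int(4 * FS))
    x[int(2 * FS)] = 1.0  # impulse at t=2
    rec = _rec(np.stack([x, x]))
    out = bandpass_filter(rec, 3, 40, mode="realtime").samples[0]
    assert np.allclose(out[: int(2 * FS)], 0.0)


# --- artifact component removal ---


def test_planted_sources_large_rms_removed(rng):
    n = int(20 * FS)
    sos_a = scipy.signal.butter(4, [8, 12], btype="bandpass", fs=FS, output="sos")
    sos_b = scipy.signal.butter(4, [20, 30], btype="bandpass", fs=FS, output="sos")
    src_a = scipy.signal.sosfilt(sos_a, rng.normal(size=n))
    src_b = scipy.signal.sosfilt(sos_b, rng.normal(size=n))
    src_a *= 10.0 / src_a.std()  # RMS 10
    src_b *= 1.0 / src_b.std()  # RMS 1
    rec = _rec(np.stack([src_a, src_b]))  # identity mixing
    out = remove_artifact_component(rec, seed=0)
    # residual power of the planted large source across both output channels
    proj = out.samples @ src_a / (src_a @ src_a)
    residual = np.outer(proj, src_a)
    assert np.sum(residual**2) / np.sum(src_a**2) < 0.01
    # the small source survives on its channel
    corr = np.corrcoef(out.samples[1], src_b)[0, 1]
    assert abs(corr) > 0.9


def test_identical_channels_degenerate():
    x = _sine(10.0)
    with pytest.raises(DegenerateInputError):
        remove_artifact_component(_rec(np.stack([x, x])))


def test_removal_deterministic(rng):
    samples = rng.normal(size=(2, int(10 * FS)))
    rec = _rec(samples)
    out1 = remove_artifact_component(rec, seed=7)
    out2 = remove_artifact_component(rec, seed=7)
    np.testing.assert_array_equal(out1.samples, out2.samples)


# --- epoching ---


def test_epoch_count_90s():
    # Oracle: direct enumeration of half-open 4-s windows at 2-s hop.
    starts = []
    t = 0.0
    while t + 4.0 <= 90.0 + 1e-9:
        starts.append(t)
        t += 2.0
    assert len(starts) == 44

    rec = _rec(np.zeros((2, int(90 * FS))))
    epochs, times = epoch_signal(rec, 4.0, 0.5)
    assert epochs.shape == (44, 2, int(4 * FS))
    np.testing.assert_allclose(times, starts)


def test_exact_length_gives_one_epoch():
    epochs, _ = epoch_signal(_rec(np.zeros((2, int(4 * FS)))), 4.0, 0.5)
    assert epochs.shape[0] == 1


def test_short_signal_gives_zero_epochs():
    epochs, _ = epoch_signal(_rec(np.zeros((2, int(3.9 * FS)))), 4.0, 0.5)
    assert epochs.shape[0] == 0


def test_bad_overlap_rejected():
    with pytest.raises(ParameterError):
        epoch_signal(_rec(np.zeros((2, 600))), 4.0, 1.0)


# --- PSD features ---


def test_feature_vector_length(rng):
    epoch = rng.normal(size=(2, int(4 * FS)))
    assert compute_psd_features(epoch, FS).shape == (219,)


def test_bin_count():
    assert len(bin_centers((4.0, 40.0), 0.5)) == 73


def test_tone_peaks_at_10hz_and_difference_is_zero():
    x = _sine(10.0, duration=4.0)
    feats = compute_psd_features(np.stack([x, x]), FS)
    centers = bin_centers()
    left, right, diff = feats[:73], feats[73:146], feats[146:]
    assert centers[np.argmax(left)] == 10.0
    assert centers[np.argmax(right)] == 10.0
    assert np.allclose(diff, 0.0)


def test_nan_epoch_rejected(rng):
    epochs = rng.normal(size=(3, 2, int(4 * FS)))
    epochs[1, 0, 5] = np.nan
    with pytest.raises(ValidationError, match="1"):
        compute_psd_matrix(epochs, FS)


def test_binning_conserves_inband_power(rng):
    # Oracle: direct periodogram integral over the 3.75-40.25 Hz band.
    x = rng.normal(size=int(120 * FS))
    f, pxx = scipy.signal.periodogram(x, fs=FS)
    band = (f >= 3.75) & (f < 40.25)
    direct = np.trapezoid(pxx[band], f[band])

    epoch = np.stack([x, np.zeros_like(x)])
    feats = compute_psd_features(epoch, FS, seg_len=2.0)
    binned_total = feats[:73].sum()
    assert binned_total == pytest.approx(direct, rel=0.01)


# --- noise metrics and flags ---


def test_identical_epochs_unflagged(rng):
    epoch = rng.normal(size=(2, int(4 * FS)))
    epochs = np.stack([epoch] * 10)
    metrics = compute_noise_metrics(epochs, FS)
    flags, _ = flag_noisy_epochs(metrics, 2.5)
    assert not flags.any()


def test_spike_epoch_flagged_via_gradient(rng):
    epochs = rng.normal(size=(51, 2, int(4 * FS)))
    epochs[7, :, 1000] += 50.0 * epochs.std()
    metrics = compute_noise_metrics(epochs, FS)
    # Oracle: direct z-computation for the max-gradient metric.
    grad = metrics.max_gradient
    z = ((grad - grad.mean(0)) / grad.std(0)).mean(axis=1)
    assert z[7] > 2.5
    flags, attribution = flag_noisy_epochs(metrics, 2.5)
    assert flags[7]
    assert attribution["max_gradient"][7]


def test_infinite_threshold_never_flags(rng):
    metrics = compute_noise_metrics(rng.normal(size=(20, 2, int(4 * FS))), FS)
    flags, _ = flag_noisy_epochs(metrics, np.inf)
    assert not flags.any()


def test_zero_variance_metric_contributes_zero():
    epochs = np.stack([np.ones((2, 100)) * k for k in range(1, 6)])
    metrics = compute_noise_metrics(epochs, FS, rms_mode="time")
    # gradient is exactly 0 in every epoch -> zero variance -> z = 0, no crash
    flags, attribution = flag_noisy_epochs(metrics, 2.5)
    assert not attribution["max_gradient"].any()


def test_noise_stats_reusable_for_streaming(rng):
    epochs = rng.normal(size=(30, 2, int(4 * FS)))
    metrics = compute_noise_metrics(epochs, FS)
    stats = NoiseStats.from_metrics(metrics)
    zs = stats.composite_z(metrics)
    for z in zs.values():
        assert abs(z.mean()) < 1e-8  # centred on the calibration statistics


# --- standardization ---


def test_standardize_unit_moments(rng):
    raw = rng.normal(size=(40, 219)) * 3 + 5
    flags = np.zeros(40, bool)
    feats, scaler = standardize_features(raw, flags)
    np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(feats.std(axis=0), 1.0, atol=1e-10)


def test_flagged_epochs_excluded_from_scaler_but_transformed(rng):
    raw = rng.normal(size=(20, 219))
    flags = np.zeros(20, bool)
    flags[3] = True
    raw[3] += 100.0
    feats, scaler = standardize_features(raw, flags)
    keep = ~flags
    np.testing.assert_allclose(feats[keep].mean(axis=0), 0.0, atol=1e-10)
    assert np.isfinite(feats[3]).all()
    assert (feats[3] > 10).mean() > 0.5  # outlier epoch stays extreme


def test_scaler_reuse_on_means_gives_zero(rng):
    raw = rng.normal(size=(10, 219))
    feats, scaler = standardize_features(raw, np.zeros(10, bool))
    np.testing.assert_allclose(scaler.transform(scaler.mean[None, :]), 0.0, atol=1e-12)


def test_zero_sd_feature_clamped(rng):
    raw = rng.normal(size=(10, 219))
    raw[:, 5] = 7.0
    feats, scaler = standardize_features(raw, np.zeros(10, bool))
    assert np.isfinite(feats[:, 5]).all()
    np.testing.assert_allclose(feats[:, 5], 0.0)


# --- pipeline-level properties ---


def test_clean_synthetic_flag_fraction_below_5pct():
    from earloop.synthetic_data import GroundTruth, generate_eeg

    truth = GroundTruth(
        w_star=np.zeros(128),
        active_set=np.array([], int),
        pleasure_intercept=50.0,
        pleasure_scale=15.0,
        score_mean=0.0,
        score_sd=0.0,
        eeg_effect=0.0,
        seed=0,
    )
    rec = generate_eeg("high", 240.0, truth, artifact_rate=0.0, seed=3)
    epochs, _ = epoch_signal(rec, 4.0, 0.5)
    metrics = compute_noise_metrics(epochs, FS)
    flags, _ = flag_noisy_epochs(metrics, 2.5)
    assert flags.mean() < 0.05


def test_artifact_epochs_mostly_flagged():
    from earloop.synthetic_data import GroundTruth, generate_eeg

    truth = GroundTruth(
        w_star=np.zeros(128),
        active_set=np.array([], int),
        pleasure_intercept=50.0,
        pleasure_scale=15.0,
        score_mean=0.0,
        score_sd=0.0,
        eeg_effect=0.0,
        seed=0,
    )
    # Mean/SD z-flagging needs sparse contamination: with a fraction f of
    # epochs touched by artifacts, the largest attainable z is
    # sqrt((1-f)/f), which crosses 2.5 only for f < 0.138. At 4-s/50% epochs
    # each artifact touches ~2 epochs, so the rate must stay below ~2/min for
    # the flag rule to see artifacts as outliers at all.
    rec = generate_eeg("high", 400.0, truth, artifact_rate=1.5, seed=5)
    art_times = [t for t, lab in rec.events if lab == "artifact"]
    assert art_times, "generator should have injected artifacts"
    epochs, starts = epoch_signal(rec, 4.0, 0.5)
    metrics = compute_noise_metrics(epochs, FS)
    flags, _ = flag_noisy_epochs(metrics, 2.5)
    covered = 0
    for t in art_times:
        overlapping = (starts <= t + 0.3) & (starts + 4.0 >= t)
        if flags[overlapping].any():
            covered += 1
    assert covered / len(art_times) > 0.8
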