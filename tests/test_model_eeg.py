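import numpy as np
import pytest

from earloop.eeg_preprocessing import EpochFeatureSet, FeatureScaler, bin_centers
from earloop.errors import ParameterError, StateError
from earloop.model_eeg import (
    EEGClassifier,
    PCScaler,
    auc_trapezoid,
    backproject_weights,
    build_training_set,
    confusion_at_half,
    evaluate_classifier,
    fit_eeg_classifier,
    permutation_test,
)


def make_featset(n, shift=0.0, seed=0, n_flagged=0):
    """Gaussian 219-dim features; class True shifted by ``shift`` on 30 dims."""
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(n, 219))
    labels = np.arange(n) % 2 == 0
    feats[labels, :30] += shift
    flags = np.zeros(n, bool)
    flags[:n_flagged] = True
    return EpochFeatureSet(
        features=feats,
        bins=bin_centers(),
        flags=flags,
        scaler=FeatureScaler(mean=np.zeros(219), sd=np.ones(219)),
        labels=labels,
    )


# --- build_training_set ---


def test_200_epochs_keep_150_components():
    balanced = build_training_set(make_featset(200), max_pcs=150, seed=0)
    assert balanced.pca_basis.shape == (219, 150)


def test_120_epochs_keep_all_components():
    balanced = build_training_set(make_featset(120), max_pcs=150, seed=0)
    assert balanced.pca_basis.shape == (219, 120)


def test_class_balancing_60_40():
    rng = np.random.default_rng(3)
    feats = rng.normal(size=(100, 219))
    labels = np.concatenate([np.ones(60, bool), np.zeros(40, bool)])
    featset = EpochFeatureSet(
        features=feats,
        bins=bin_centers(),
        flags=np.zeros(100, bool),
        scaler=FeatureScaler(mean=np.zeros(219), sd=np.ones(219)),
        labels=labels,
    )
    balanced = build_training_set(featset, seed=0)
    assert balanced.labels.sum() == 40
    assert (~balanced.labels).sum() == 40


def test_flagged_epochs_dropped():
    balanced = build_training_set(make_featset(60, n_flagged=10), seed=0)
    assert balanced.scores.shape[0] <= 50


def test_single_class_rejected():
    featset = make_featset(40)
    featset.labels = np.ones(40, bool)
    with pytest.raises(ParameterError):
        build_training_set(featset, seed=0)


def test_pc_scores_standardized():
    balanced = build_training_set(make_featset(80), seed=0)
    # scaler was fitted pre-balancing, so post-balancing moments are close
    assert np.abs(balanced.scores.mean(axis=0)).max() < 0.5


# --- fit / evaluate ---


def test_separable_classes_high_test_accuracy():
    balanced = build_training_set(make_featset(200, shift=2.0), max_pcs=30, seed=0)
    model = fit_eeg_classifier(balanced, cv_folds=5, seed=0)
    assert model.validation["test_acc"] >= 0.9
    assert model.validation["test_auc"] >= 0.9


def test_null_labels_chance_auc():
    aucs = []
    for seed in range(20):
        balanced = build_training_set(make_featset(120, shift=0.0, seed=seed), max_pcs=20, seed=seed)
        model = fit_eeg_classifier(
            balanced, cv_folds=3, lambda_grid=np.array([0.05]), seed=seed
        )
        aucs.append(model.validation["test_auc"])
    assert 0.3 <= np.mean(aucs) <= 0.7


def test_huge_lambda_constant_probability():
    balanced = build_training_set(make_featset(60, shift=1.0), max_pcs=10, seed=0)
    model = fit_eeg_classifier(balanced, cv_folds=3, lambda_grid=np.array([1e6]), seed=0)
    np.testing.assert_allclose(model.gamma, 0.0)
    p = model.decode_scores(balanced.scores)
    assert np.allclose(p, p[0])


def test_too_few_epochs_rejected():
    balanced = build_training_set(make_featset(18), seed=0)
    with pytest.raises(ParameterError):
        fit_eeg_classifier(balanced, seed=0)


def test_holdout_never_in_training():
    balanced = build_training_set(make_featset(80), max_pcs=10, seed=0)
    model = fit_eeg_classifier(balanced, cv_folds=3, lambda_grid=np.array([0.05]), seed=0)
    assert set(model.train_idx).isdisjoint(model.test_idx)
    assert len(model.train_idx) + len(model.test_idx) == balanced.scores.shape[0]


def test_perfect_predictions_metrics():
    y = np.array([1, 1, 0, 0], bool)
    p = np.array([0.9, 0.8, 0.2, 0.1])
    conf = confusion_at_half(y, p)
    assert conf == {"tp": 2, "fp": 0, "fn": 0, "tn": 2}
    assert auc_trapezoid(y, p) == pytest.approx(1.0)


def test_independent_predictions_chance_auc(rng):
    y = rng.random(4000) > 0.5
    p = rng.random(4000)
    assert auc_trapezoid(y, p) == pytest.approx(0.5, abs=0.05)


def test_auc_pair_enumeration_oracle():
    # Oracle: AUC = P(score_pos > score_neg) + 0.5 P(tie), enumerated.
    scores = np.array([0.9, 0.8, 0.4, 0.1])
    labels = np.array([1, 0, 1, 0], bool)
    wins = ties = 0
    pos = scores[labels]
    neg = scores[~labels]
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
    assert oracle == 0.75
    assert auc_trapezoid(labels, scores) == pytest.approx(oracle)


def test_evaluate_requires_fit():
    balanced = build_training_set(make_featset(40), seed=0)
    with pytest.raises(StateError):
        evaluate_classifier(EEGClassifier(), balanced)


# --- permutation test ---


def test_permutation_p_zero_on_separable():
    balanced = build_training_set(make_featset(200, shift=3.0), max_pcs=20, seed=0)
    model = fit_eeg_classifier(balanced, cv_folds=3, lambda_grid=np.array([0.01]), seed=0)
    assert model.validation["test_auc"] == 1.0
    p, null = permutation_test(balanced, model, n_perm=200, seed=0)
    assert p == 0.0
    assert len(null) == 200


def test_permutation_zero_perms_rejected():
    balanced = build_training_set(make_featset(40, shift=1.0), max_pcs=5, seed=0)
    model = fit_eeg_classifier(balanced, cv_folds=3, lambda_grid=np.array([0.05]), seed=0)
    with pytest.raises(ParameterError):
        permutation_test(balanced, model, n_perm=0)


# --- back-projection ---


def _toy_model(gamma, sd=None, basis=None, k=None):
    k = k if k is not None else len(gamma)
    basis = basis if basis is not None else np.random.default_rng(0).normal(size=(219, k))
    sd = sd if sd is not None else np.ones(k)
    return EEGClassifier(
        pca_basis=basis,
        pca_mean=np.zeros(219),
        pc_scaler=PCScaler(mean=np.zeros(k), sd=sd),
        gamma0=0.0,
        gamma=np.asarray(gamma, dtype=float),
        lam=0.1,
        fitted=True,
    )


def test_single_component_weight_proportional_to_loading():
    model = _toy_model([2.0, 0.0, 0.0])
    wmap = backproject_weights(model)
    expected = 2.0 * model.pca_basis[:, 0]
    np.testing.assert_allclose(wmap.weights.T.reshape(-1), expected, atol=1e-12)


def test_zero_gamma_zero_map():
    wmap = backproject_weights(_toy_model([0.0, 0.0]))
    np.testing.assert_allclose(wmap.weights, 0.0)
    assert all(v == 0.0 for v in wmap.band_means.values())


def test_identity_basis_unit_gamma():
    gamma = np.zeros(219)
    gamma[4] = 1.0
    model = _toy_model(gamma, basis=np.eye(219), k=219)
    wmap = backproject_weights(model)
    assert wmap.weights[4, 0] == 1.0  # bin 5 of the first derivation
    assert np.count_nonzero(wmap.weights) == 1


def test_band_means_cover_published_bands():
    wmap = backproject_weights(_toy_model([1.0, -1.0]))
    assert set(wmap.band_means) == {"theta", "alpha", "beta", "gamma"}


def test_backprojection_reconstruction_identity():
    # "divide" convention yields the literal linear weight of the decoder:
    # logit differences equal feature-space inner products with the map.
    rng = np.random.default_rng(5)
    balanced = build_training_set(make_featset(80, shift=1.0), max_pcs=15, seed=0)
    model = fit_eeg_classifier(balanced, cv_folds=3, lambda_grid=np.array([0.02]), seed=0)
    wmap = backproject_weights(model, convention="divide")
    w = wmap.weights.T.reshape(-1)
    f1, f2 = rng.normal(size=(2, 219))
    logit = lambda p: np.log(p / (1 - p))
    d_model = logit(model.decode_features(f1[None, :])[0]) - logit(
        model.decode_features(f2[None, :])[0]
    )
    assert d_model == pytest.approx(float((f1 - f2) @ w), abs=1e-10)


def test_missing_basis_rejected():
    with pytest.raises(StateError):
        backproject_weights(EEGClassifier(gamma=np.ones(3), fitted=True))


# --- pipeline properties ---


def test_decode_invariant_to_epoch_order(rng):
    balanced = build_training_set(make_featset(60, shift=1.0), max_pcs=10, seed=0)
    model = fit_eeg_classifier(balanced, cv_folds=3, lambda_grid=np.array([0.05]), seed=0)
    feats = rng.normal(size=(20, 219))
    perm = rng.permutation(20)
    p1 = model.decode_features(feats)
    p2 = model.decode_features(feats[perm])
    np.testing.assert_allclose(p1[perm], p2, atol=1e-12)


def test_auc_monotone_in_eeg_effect():
    from earloop.eeg_preprocessing import build_feature_set
    from earloop.synthetic_data import GroundTruth, generate_eeg

    aucs = []
    for effect in (0.1, 0.6, 2.0):
        truth = GroundTruth(
            w_star=np.zeros(128),
            active_set=np.array([], int),
            pleasure_intercept=50.0,
            pleasure_scale=15.0,
            score_mean=0.0,
            score_sd=0.0,
            eeg_effect=effect,
            seed=0,
        )
        recs = []
        for k in range(2):
            recs.append((generate_eeg("high", 120.0, truth, seed=10 + k), True))
            recs.append((generate_eeg("low", 120.0, truth, seed=20 + k), False))
        featset, _ = build_feature_set(recs, seed=0)
        balanced = build_training_set(featset, max_pcs=30, seed=0)
        model = fit_eeg_classifier(
            balanced, cv_folds=5, lambda_grid=np.geomspace(0.1, 1e-3, 10), seed=0
        )
        aucs.append(model.validation["test_auc"])
    assert aucs[0] < aucs[1] < aucs[2] or (aucs[0] < aucs[1] and aucs[2] == 1.0 == aucs[1])
    assert aucs[2] > 0.9
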