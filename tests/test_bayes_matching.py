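"""Template bank: fitting, evidence contracts, symmetry, cross-validation."""

import numpy as np
import pytest

from biomotion import bayes_matching as bmx


def synthetic_features(rng, direction, n_pairs=89, n_feat=12, sep=2.0,
                       noise=0.3):
    """Separable toy features: direction shifts a subset of detectors,
    window index shifts another (so windows are discriminable too)."""
    win = np.array([bmx.window_of_pair(k) for k in range(n_pairs)])
    base = np.zeros((n_pairs, n_feat))
    base[:, :4] = (sep if direction == "right" else -sep)
    base[np.arange(n_pairs), 4 + (win % (n_feat - 4))] += 1.0
    return base + noise * rng.normal(size=(n_pairs, n_feat))


@pytest.fixture()
def toy_bank(rng):
    feats, labels = [], []
    for d in ("left", "right"):
        for _ in range(6):
            feats.append(synthetic_features(rng, d))
            labels.append(d)
    return bmx.fit_templates(feats, labels), feats, labels


def test_bank_structure(toy_bank):
    bank, _, _ = toy_bank
    assert bank.means.shape == (18, 12)
    assert np.all(bank.variances > 0)
    assert bank.margin_scale.shape == (9,)


def test_windows_partition_the_frames():
    windows = [bmx.window_of_pair(k) for k in range(89)]
    counts = np.bincount(windows)
    assert list(counts) == [9] + [10] * 8
    assert bmx.template_index("right", 0) == 0
    assert bmx.template_index("left", 8) == 17


def test_identical_sequences_floor_dispersion(rng):
    f = synthetic_features(rng, "right", noise=0.0)
    g = synthetic_features(rng, "left", noise=0.0)
    bank = bmx.fit_templates([f, f, g, g], ["right", "right", "left", "left"])
    assert np.all(bank.variances == bank.config.var_floor)
    np.testing.assert_allclose(bank.means[0], f[:9].mean(axis=0))


def test_feature_dimension_follows_training(rng):
    for n_feat in (80, 100):
        feats = [synthetic_features(rng, d, n_feat=n_feat)
                 for d in ("left", "left", "right", "right")]
        bank = bmx.fit_templates(feats, ["left", "left", "right", "right"])
        assert bank.n_features == n_feat
    with pytest.raises(ValueError):
        bank.raw_score(np.zeros(13))


def test_training_order_invariance(rng):
    feats = [synthetic_features(rng, d) for d in
             ("left", "right", "left", "right")]
    labels = ["left", "right", "left", "right"]
    b1 = bmx.fit_templates(feats, labels)
    order = [3, 1, 2, 0]
    b2 = bmx.fit_templates([feats[i] for i in order],
                           [labels[i] for i in order])
    np.testing.assert_allclose(b1.means, b2.means)
    np.testing.assert_allclose(b1.variances, b2.variances)
    np.testing.assert_allclose(b1.margin_scale, b2.margin_scale)


def test_too_few_sequences_rejected(rng):
    f = synthetic_features(rng, "right")
    with pytest.raises(ValueError):
        bmx.fit_templates([f, f, f], ["right", "right", "left"])


def test_at_mean_feature_maximizes_raw_score_in_window(toy_bank):
    bank, _, _ = toy_bank
    for j in (0, 4, 8):
        i = bmx.template_index("right", j)
        raw = bank.raw_score(bank.means[i])
        assert raw[i] >= raw[bmx.template_index("left", j)]


def test_lambda_zero_is_pure_loglikelihood_ranking(rng):
    feats = [synthetic_features(rng, d) for d in
             ("left", "left", "right", "right")]
    labels = ["left", "left", "right", "right"]
    bank = bmx.fit_templates(feats, labels,
                             bmx.TemplateConfig(lambda_risk=0.0))
    x = feats[0][3]
    raw = bank.raw_score(x)
    loglik = np.array([
        -0.5 * np.sum((x - bank.means[i]) ** 2 / bank.variances[i])
        - 0.5 * np.sum(np.log(bank.variances[i])) for i in range(18)])
    np.testing.assert_allclose(np.argsort(raw), np.argsort(loglik))
    np.testing.assert_allclose(raw, loglik, rtol=1e-12)


def test_dispersion_penalty_lowers_at_mean_score(toy_bank):
    # closed form: at the template mean, raw = -(1+lambda)/2 * sum log s^2,
    # so doubling the dispersion lowers the score when lambda > 0
    bank, _, _ = toy_bank
    assert bank.config.lambda_risk > 0
    i = 0
    raw_before = bank.raw_score(bank.means[i])[i]
    expected = -0.5 * (1 + bank.config.lambda_risk) * np.sum(
        np.log(bank.variances[i]))
    assert raw_before == pytest.approx(expected)
    bank.variances = bank.variances.copy()
    bank.variances[i] *= 2.0
    raw_after = bank.raw_score(bank.means[i])[i]
    assert raw_after < raw_before


def test_mirror_symmetric_training_gives_symmetric_bank(model):
    bank = model.bank
    # left-template means equal the mirrored right-template means under the
    # detector mirror permutation (training data are exact mirror pairs)
    from biomotion.opponent_motion import KINDS
    layout = model.layout
    perm = np.empty(100, dtype=int)
    for kind in KINDS:
        sl = layout.kind_slice(kind)
        target_kind = {"cw": "ccw", "ccw": "cw"}.get(kind, kind)
        tl = layout.kind_slice(target_kind)
        idx = np.arange(sl.start, sl.stop).reshape(5, -1)
        perm[np.arange(tl.start, tl.stop).reshape(5, -1)] = idx[:, ::-1]
    for j in range(9):
        i_r = bmx.template_index("right", j)
        i_l = bmx.template_index("left", j)
        np.testing.assert_allclose(bank.means[i_l], bank.means[i_r][perm],
                                   atol=1e-10)


def test_evidence_stream_shape_and_range(model):
    g = model.evidence_for("right", 8.0)
    lo, hi = model.bank.config.evidence_range
    assert g.shape == (89, 18)
    assert np.all(g >= lo) and np.all(g <= hi)


def test_evidence_mirror_equivariance(model):
    gr = model.evidence_for("right", 8.0)
    gl = model.evidence_for("left", 8.0)
    np.testing.assert_allclose(gr[:, :9], gl[:, 9:], atol=1e-9)
    np.testing.assert_allclose(gr[:, 9:], gl[:, :9], atol=1e-9)


def test_crossvalidation_separable_and_structure(rng):
    feats, labels = [], []
    for d in ("left", "right"):
        for _ in range(10):
            feats.append(synthetic_features(rng, d))
            labels.append(d)
    report = bmx.crossvalidate(feats, labels, k=5, seed=1)
    assert len(report.fold_accuracies) == 5
    assert report.mean == 1.0
    all_test = np.sort(np.concatenate(report.folds))
    assert np.array_equal(all_test, np.arange(20))  # folds partition


def test_crossvalidation_random_labels_near_chance(rng):
    feats, labels = [], []
    for _ in range(20):
        d = rng.choice(["left", "right"])
        feats.append(synthetic_features(rng, rng.choice(["left", "right"])))
        labels.append(d)
    if len(set(labels)) < 2 or min(labels.count(x) for x in set(labels)) < 5:
        pytest.skip("degenerate random draw")
    report = bmx.crossvalidate(feats, labels, k=5, seed=2)
    # binomial 95% band around 0.5 for n = 20
    assert 0.2 <= report.mean <= 0.8
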