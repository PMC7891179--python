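"""Normalization, FDR, PLS2, selection, model search and the CV loop."""

import numpy as np
import pandas as pd
import pytest

from oculomet.classifier import (
    PipelineConfig,
    Standardizer,
    candidate_models,
    cv_confidence_loop,
    external_validate,
    fdr_scores,
    fit_pair_classifier,
    pls2_fit,
    pls2_project,
    search_models,
    select_training_features,
    zscore_fit_apply,
)
from oculomet.protocol_io import TABLE_FEATURES
from oculomet.synthetic_gaze import sample_feature_matrix


def _clouds(rng, n=30, d=4.0, p=5):
    """Two Gaussian clouds separated by d along every axis."""
    a = rng.normal(0, 1, (n, p))
    b = rng.normal(d, 1, (n, p))
    x = pd.DataFrame(np.vstack([a, b]), columns=[f"f{i}" for i in range(p)])
    y = np.array(["neg"] * n + ["pos"] * n)
    return x, y


# ---------------------------------------------------------------------------
# z-normalization
# ---------------------------------------------------------------------------


def test_zscore_hand_arithmetic():
    z, = zscore_fit_apply(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
    assert np.allclose(z.ravel(), [-1.0, 0.0, 1.0])  # sample SD = 1


def test_zscore_constant_column_names_feature():
    with pytest.raises(ValueError, match="'flat'"):
        Standardizer().fit(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


def test_zscore_heldout_uses_training_statistics():
    train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    held = pd.DataFrame({"a": [4.0]})
    _, zh = zscore_fit_apply(train, held)
    assert zh.ravel()[0] == pytest.approx((4.0 - 2.0) / 1.0)


# ---------------------------------------------------------------------------
# Fisher discriminant ratio
# ---------------------------------------------------------------------------


def test_fdr_plug_in_value(rng):
    # mu1=1, mu2=0, var1=var2=0.5 -> (1-0)^2 / (0.5+0.5) = 1
    a = rng.normal(size=4000)
    x = pd.DataFrame({"f": np.concatenate([1 + a * np.sqrt(0.5), a[::-1] * np.sqrt(0.5)])})
    y = np.array([1] * 4000 + [2] * 4000)
    s = fdr_scores(x, y)[0]
    assert s.score == pytest.approx(1.0, abs=0.1)


def test_fdr_zero_iff_equal_means():
    x = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
    y = np.array([0, 0, 0, 1, 1, 1])
    s = fdr_scores(x, y)[0]
    assert s.score == 0.0
    assert not s.infinite


def test_fdr_affine_invariance(rng):
    raw = rng.normal(size=40)
    y = np.array([0] * 20 + [1] * 20)
    raw[y == 1] += 2.0
    s1 = fdr_scores(pd.DataFrame({"f": raw}), y)[0].score
    s2 = fdr_scores(pd.DataFrame({"f": 3.5 * raw - 11.0}), y)[0].score
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_fdr_infinite_separation_flagged():
    x = pd.DataFrame({"f": [1.0, 1.0, 2.0, 2.0]})
    y = np.array([0, 0, 1, 1])
    s = fdr_scores(x, y)[0]
    assert s.infinite
    assert s.score == np.inf


# ---------------------------------------------------------------------------
# PLS2
# ---------------------------------------------------------------------------


@pytest.fixture()
def normalized_blocks(rng):
    x = rng.normal(size=(20, 6))
    y = rng.normal(size=(20, 3))
    for m in (x, y):
        m -= m.mean(0)
        m /= m.std(0, ddof=1)
    return x, y


def test_pls2_decomposition_identities(normalized_blocks):
    x, y = normalized_blocks
    m = pls2_fit(x, y, 4)
    assert np.linalg.norm(x - m.T @ m.P.T - m.E) < 1e-8
    assert np.linalg.norm(y - m.U @ m.Q.T - m.F) < 1e-8
    gram = m.T.T @ m.T
    assert np.max(np.abs(gram - np.diag(np.diag(gram)))) < 1e-8


def test_pls2_full_rank_reconstruction_matches_svd_oracle(normalized_blocks):
    x, y = normalized_blocks
    rank = np.linalg.matrix_rank(x)  # SVD-based oracle for the exact rank
    m = pls2_fit(x, y, rank)
    assert np.linalg.norm(m.E) / np.linalg.norm(x) < 1e-8


def test_pls2_identity_target_leaves_no_residual(normalized_blocks):
    x, _ = normalized_blocks
    m = pls2_fit(x, x, np.linalg.matrix_rank(x))
    assert np.linalg.norm(x - m.U @ m.Q.T - m.F) < 1e-8
    assert np.linalg.norm(m.F) / np.linalg.norm(x) < 1e-8


def test_pls2_recovers_collinear_direction(rng):
    v = rng.normal(size=4)
    v /= np.linalg.norm(v)
    scores = rng.normal(size=(30, 1))
    x = scores @ v[None, :]
    m = pls2_fit(x, scores, 1)
    assert abs(m.W[:, 0] @ v) == pytest.approx(1.0, abs=1e-8)


def test_pls2_projection_reproduces_training_scores(normalized_blocks):
    x, y = normalized_blocks
    m = pls2_fit(x, y, 3)
    assert np.max(np.abs(pls2_project(m, x) - m.T)) < 1e-8


def test_pls2_component_count_validated(normalized_blocks):
    x, y = normalized_blocks
    with pytest.raises(ValueError, match="n_components"):
        pls2_fit(x, y, 10)


def test_pls2_agrees_with_reference_implementation(normalized_blocks):
    """Scores from an independent NIPALS implementation correlate to ~1."""
    from sklearn.cross_decomposition import PLSRegression

    x, y = normalized_blocks
    ours = pls2_fit(x, y, 3)
    ref = PLSRegression(n_components=3, scale=False).fit(x, y)
    for k in range(3):
        c = np.corrcoef(ref.x_scores_[:, k], ours.T[:, k])[0, 1]
        assert abs(c) > 0.999


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def test_selection_threshold_and_missing_values(rng):
    n = 30
    y = np.array(["a"] * n + ["b"] * n)
    strong = np.concatenate([rng.normal(0, 1, n), rng.normal(5, 1, n)])
    weak = np.concatenate([rng.normal(0, 1, n), rng.normal(0.7, 1, n)])
    gappy = strong.copy()
    gappy[3] = np.nan
    x = pd.DataFrame({"strong": strong, "weak": weak, "gappy": gappy})
    from scipy.stats import ttest_ind

    p_weak = ttest_ind(weak[:n], weak[n:]).pvalue
    assert p_weak > 0.001  # the weak feature indeed misses the bar
    kept = select_training_features(x, y, p_threshold=0.001)
    assert kept == ["strong"]  # weak: p >= 1e-3; gappy: missing value


def test_selection_empty_advises_relaxation(rng):
    x = pd.DataFrame({"f": rng.normal(size=20)})
    y = np.array(["a"] * 10 + ["b"] * 10)
    with pytest.raises(ValueError, match="relax"):
        select_training_features(x, y, p_threshold=1e-9)


# ---------------------------------------------------------------------------
# Model search and the confidence loop
# ---------------------------------------------------------------------------


def test_search_models_separable_data_wins_with_perfect_auc(rng):
    x, y = _clouds(rng, n=20, d=5.0)
    name, est = search_models(x, y, seed=3)
    report = cv_confidence_loop(
        x, y, PipelineConfig(model=name, iterations=50), seed=3
    )
    assert report.best_auc == report.worst_auc == report.mean_auc == 1.0
    assert report.mean_accuracy == 1.0


def test_search_models_deterministic_under_seed(rng):
    x, y = _clouds(rng, n=15, d=1.5)
    assert search_models(x, y, seed=9)[0] == search_models(x, y, seed=9)[0]


def test_confidence_loop_order_statistics_and_determinism(rng):
    x, y = _clouds(rng, n=15, d=1.0)
    cfg = PipelineConfig(model="svm_linear", p_threshold=0.5, iterations=60)
    r1 = cv_confidence_loop(x, y, cfg, seed=21)
    r2 = cv_confidence_loop(x, y, cfg, seed=21)
    assert r1.worst_auc <= r1.mean_auc <= r1.best_auc
    assert 0.0 <= r1.worst_auc and r1.best_auc <= 1.0
    assert r1.as_dict() == r2.as_dict()


def test_confidence_loop_requires_five_per_class(rng):
    x, y = _clouds(rng, n=4, d=3.0)
    with pytest.raises(ValueError, match=">= 5 subjects"):
        cv_confidence_loop(x, y, PipelineConfig(iterations=5), seed=1)


def test_permutation_null_mean_auc_near_half(profiles):
    """With labels shuffled, the loop's mean AUC sits at 0.5 +- 0.05."""
    rng = np.random.default_rng(1717)
    df = sample_feature_matrix(profiles, {"AD": 18, "control": 29}, seed=55)
    y = df["group"].to_numpy().copy()
    rng.shuffle(y)
    cfg = PipelineConfig(model="svm_linear", selection="cohort",
                         p_threshold=1.0, iterations=1000)
    report = cv_confidence_loop(df[list(TABLE_FEATURES)], y, cfg, seed=77)
    assert abs(report.mean_auc - 0.5) < 0.05


def test_candidate_grid_contains_required_models():
    names = {name for name, _, _ in candidate_models()}
    assert {"svm_linear", "svm_rbf", "knn_1", "knn_3", "knn_5", "knn_7"} <= names


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------


def test_external_validation_consistency_and_degradation(profiles, rng):
    train = sample_feature_matrix(profiles, {"AD": 18, "control": 29}, seed=8)
    x, y = train[list(TABLE_FEATURES)], train["group"].to_numpy()
    clf = fit_pair_classifier(x, y, PipelineConfig(model="svm_linear"))

    # external copy of the training cohort reproduces resubstitution AUC
    resub = external_validate(clf, x, y)
    from sklearn.metrics import roc_auc_score

    direct = roc_auc_score((y == clf.classes[1]).astype(int), clf.decision_scores(x))
    assert resub["auc"] == pytest.approx(direct)

    # in-distribution external sample
    ext = sample_feature_matrix(profiles, {"AD": 15, "control": 15}, seed=9)
    indist = external_validate(clf, ext[list(TABLE_FEATURES)], ext["group"].to_numpy())

    # shifted external sample: a much milder phenotype, with means and SDs
    # pulled 90% toward the control distribution
    shifted_profile = profiles["AD"].with_features(
        {
            name: (
                0.1 * profiles["AD"].mean(name) + 0.9 * profiles["control"].mean(name),
                0.1 * profiles["AD"].sd(name) + 0.9 * profiles["control"].sd(name),
            )
            for name in TABLE_FEATURES
        }
    )
    ext2 = sample_feature_matrix(
        {"AD": shifted_profile, "control": profiles["control"]},
        {"AD": 15, "control": 15},
        seed=9,
    )
    shifted = external_validate(clf, ext2[list(TABLE_FEATURES)], ext2["group"].to_numpy())
    assert shifted["auc"] < indist["auc"]
    assert len(shifted["calls"]) == 30


def test_external_validation_fifteen_subject_cohort(profiles):
    train = sample_feature_matrix(profiles, {"AD": 18, "control": 29}, seed=12)
    clf = fit_pair_classifier(
        train[list(TABLE_FEATURES)], train["group"].to_numpy(),
        PipelineConfig(model="svm_linear"),
    )
    ext = sample_feature_matrix(profiles, {"AD": 15}, seed=13)
    res = external_validate(clf, ext[list(TABLE_FEATURES)], ext["group"].to_numpy())
    assert len(res["calls"]) == 15
    assert np.isnan(res["auc"])  # single-class external sample: AUC undefined


def test_external_validation_missing_feature_named(profiles):
    train = sample_feature_matrix(profiles, {"AD": 18, "control": 29}, seed=14)
    clf = fit_pair_classifier(
        train[list(TABLE_FEATURES)], train["group"].to_numpy(),
        PipelineConfig(model="svm_linear"),
    )
    ext = train.drop(columns=[clf.features[0]])
    with pytest.raises(ValueError, match=clf.features[0]):
        external_validate(clf, ext, train["group"].to_numpy())
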