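"""Scaling, PCA, OPLS-DA, Q2 cross-validation, CV-ANOVA and permutation test."""
import numpy as np
import pytest

from metabopair import (
    cross_validated_q2,
    cv_anova,
    fit_oplsda,
    fit_pca,
    permutation_test,
    scale_matrix,
    select_n_ortho,
    validate_model,
)


def two_class_data(n_per_class=20, n_features=40, shift=2.0, frac_informative=0.2, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    k = int(frac_informative * n_features)
    X[n_per_class:, :k] += shift
    y = ["a"] * n_per_class + ["b"] * n_per_class
    return X, y


# -- scaling ----------------------------------------------------------------


def test_uv_scaling_unit_sd_and_roundtrip():
    rng = np.random.default_rng(1)
    X = rng.lognormal(2, 1, size=(15, 8))
    scaled = scale_matrix(X, "uv")
    np.testing.assert_allclose(scaled.X.std(axis=0, ddof=1), 1.0)
    np.testing.assert_allclose(scaled.X.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(scaled.inverse_transform(scaled.X), X)


def test_center_only_and_zero_variance_drop():
    X = np.column_stack([np.arange(6.0), np.full(6, 3.0), np.arange(6.0) ** 2])
    scaled = scale_matrix(X, "center_only", feature_ids=["a", "b", "c"])
    assert scaled.dropped == ["b"]
    np.testing.assert_allclose(scaled.X.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(scaled.X.std(axis=0, ddof=1), X[:, [0, 2]].std(axis=0, ddof=1))
    with pytest.raises(ValueError):
        scale_matrix(np.ones((5, 3)), "uv")


# -- PCA --------------------------------------------------------------------


def test_pca_perfect_line_explains_everything():
    t = np.linspace(-2, 2, 9)
    X = np.column_stack([t, 2 * t, -t])
    model = fit_pca(scale_matrix(X, "center_only"), 1)
    assert model.r2x[0] == pytest.approx(1.0)


def test_pca_reconstruction_and_variance_oracle():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(5, 4))
    scaled = scale_matrix(X, "center_only")
    k = min(scaled.X.shape)
    model = fit_pca(scaled, k)
    np.testing.assert_allclose(model.scores @ model.loadings.T, scaled.X, atol=1e-10)
    # oracle: eigendecomposition of the covariance
    evals = np.sort(np.linalg.eigvalsh(scaled.X.T @ scaled.X))[::-1]
    np.testing.assert_allclose(model.r2x, evals[:k] / (scaled.X**2).sum(), atol=1e-10)
    assert model.r2x.sum() <= 1.0 + 1e-12
    # deterministic sign convention: largest-magnitude loading element positive
    for a in range(k):
        j = np.argmax(np.abs(model.loadings[:, a]))
        assert model.loadings[j, a] > 0


# -- OPLS-DA ----------------------------------------------------------------


def nipals_pls1_first_component(X, y):
    """Oracle: first NIPALS PLS1 component for a single centered response."""
    w = X.T @ y
    w /= np.linalg.norm(w)
    t = X @ w
    return w, t


def test_opls_zero_ortho_equals_pls1():
    rng = np.random.default_rng(11)
    for _ in range(5):
        X = rng.normal(size=(10, 8))
        y = ["a"] * 5 + ["b"] * 5
        scaled = scale_matrix(X, "uv")
        model = fit_oplsda(scaled.X, y, n_ortho=0)
        coded = np.array([-1.0] * 5 + [1.0] * 5)
        w_ref, t_ref = nipals_pls1_first_component(scaled.X, coded - coded.mean())
        np.testing.assert_allclose(np.abs(model.w), np.abs(w_ref), atol=1e-10)
        np.testing.assert_allclose(np.abs(model.t), np.abs(t_ref), atol=1e-10)


def test_opls_orthogonality_invariant():
    X, y = two_class_data(seed=3)
    scaled = scale_matrix(X, "uv")
    model = fit_oplsda(scaled.X, y, n_ortho=3)
    for a in range(model.n_ortho):
        t_o = model.T_o[:, a]
        cos = abs(model.t @ t_o) / (np.linalg.norm(model.t) * np.linalg.norm(t_o))
        assert cos < 1e-8


def test_opls_strong_separation_high_r2y():
    X, y = two_class_data(shift=5.0, seed=4)
    model = fit_oplsda(scale_matrix(X, "uv").X, y, n_ortho=1)
    assert model.r2y > 0.9


def test_opls_no_signal_raises():
    # y exactly orthogonal to every column
    X = np.array([[1.0, 2.0], [1.0, 2.0], [-1.0, -2.0], [-1.0, -2.0]])
    y = ["a", "b", "a", "b"]  # coded y orthogonal to both columns
    with pytest.raises(ValueError, match="orthogonal"):
        fit_oplsda(X - X.mean(axis=0), y, n_ortho=0)


def test_opls_requires_two_classes():
    with pytest.raises(ValueError, match="2 classes"):
        fit_oplsda(np.eye(4), ["a", "a", "a", "a"], 0)


# -- Q2 cross-validation ----------------------------------------------------


def test_q2_perfect_prediction_limit():
    # y duplicated into X columns: prediction is deterministic
    coded = np.array([-1.0, 1.0] * 10)
    X = np.column_stack([coded, coded, coded]) + 1e-9
    y = ["a" if v < 0 else "b" for v in coded]
    cv = cross_validated_q2(X, y, n_ortho=0, folds=5, seed=0)
    assert cv.q2 > 0.99


def test_q2_null_near_zero_on_average():
    rng = np.random.default_rng(0)
    q2s = []
    for seed in range(100):
        X = rng.normal(size=(20, 10))
        y = list(rng.permutation(["a"] * 10 + ["b"] * 10))
        q2s.append(cross_validated_q2(X, y, n_ortho=0, folds=5, seed=seed).q2)
    assert np.mean(q2s) <= 0.05


def test_q2_strong_signal_exceeds_acceptability_threshold():
    X, y = two_class_data(shift=5.0, seed=9)
    cv = cross_validated_q2(scale_matrix(X, "uv").X, y, n_ortho=0, folds=7, seed=1)
    assert cv.q2 >= 0.5


def test_q2_class_relabeling_symmetry():
    X, y = two_class_data(seed=13)
    Xs = scale_matrix(X, "uv").X
    q2_ab = cross_validated_q2(Xs, y, 1, folds=7, seed=5).q2
    swapped = ["b" if v == "a" else "a" for v in y]
    q2_ba = cross_validated_q2(Xs, swapped, 1, folds=7, seed=5).q2
    assert q2_ab == pytest.approx(q2_ba, abs=1e-10)


def test_q2_seed_reproducible(small_study):
    X, y = two_class_data(seed=2)
    a = cross_validated_q2(X, y, 1, folds=7, seed=3)
    b = cross_validated_q2(X, y, 1, folds=7, seed=3)
    assert a.q2 == b.q2
    np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)


# -- CV-ANOVA ---------------------------------------------------------------


def test_cv_anova_degenerate_limits():
    assert cv_anova(press=10.0, ss_tot=10.0, n_samples=20, n_components=1) == 1.0
    assert cv_anova(press=1e-12, ss_tot=10.0, n_samples=20, n_components=1) < 1e-10
    with pytest.raises(ValueError):
        cv_anova(press=1.0, ss_tot=2.0, n_samples=3, n_components=2)


def test_cv_anova_size_under_null():
    """Rejection rate at alpha = 0.05 stays near nominal on null data."""
    rng = np.random.default_rng(17)
    rejections = 0
    n_seeds = 200
    for seed in range(n_seeds):
        X = rng.normal(size=(24, 6))
        y = ["a"] * 12 + ["b"] * 12
        cv = cross_validated_q2(X, y, n_ortho=0, folds=6, seed=seed)
        p = cv_anova(cv.press, cv.ss_tot, 24, n_components=1)
        rejections += p < 0.05
    assert 0.01 <= rejections / n_seeds <= 0.12


# -- permutation test -------------------------------------------------------


def test_permutation_identity_reproduces_observed():
    X, y = two_class_data(seed=21)
    Xs = scale_matrix(X, "uv").X
    model = fit_oplsda(Xs, y, n_ortho=0)
    r2_again = fit_oplsda(Xs, list(y), n_ortho=0).r2y
    assert r2_again == model.r2y


def test_permutation_p_floor_and_strong_signal():
    X, y = two_class_data(shift=5.0, seed=23)
    Xs = scale_matrix(X, "uv").X
    perm = permutation_test(Xs, y, n_iter=99, seed=1, n_ortho=0, folds=5)
    assert perm.p_q2 == pytest.approx(1 / 100)  # beats all 99 permutations
    assert perm.p_r2 >= 1 / 100
    # reproducible from the seed
    again = permutation_test(Xs, y, n_iter=99, seed=1, n_ortho=0, folds=5)
    np.testing.assert_array_equal(perm.q2_perm, again.q2_perm)


def test_validate_model_strong_signal_passes_battery():
    X, y = two_class_data(shift=5.0, seed=31)
    Xs = scale_matrix(X, "uv").X
    n_ortho, _ = select_n_ortho(Xs, y, max_ortho=2, folds=7, seed=0)
    model, cv, report = validate_model(
        Xs, y, n_ortho=n_ortho, folds=7, n_permutations=99, seed=0
    )
    assert report.q2_threshold_passed
    assert report.cv_anova_p < 0.05
    assert report.permutation.p_q2 < 0.05
    assert report.overall_valid
    assert cv.q2 <= model.r2y + 1e-9
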