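"""PCA diagnostics and OPLS-DA with its validation battery.

OPLS-DA splits the scaled data matrix into one predictive latent component,
correlated with the (binary, dummy-coded) class vector, plus a small number
of orthogonal components carrying class-unrelated structure. Model quality
is judged the way the chemometrics literature prescribes: R2Y (fraction of
class variance fitted), Q2 (fraction predicted under stratified K-fold
cross-validation, acceptable above 0.5), CV-ANOVA on the cross-validated
predictive residuals, and a label-permutation test on R2 and Q2.

The O-PLS deflation follows Trygg & Wold's NIPALS-style algorithm for a
single response: w ~ X'y; per orthogonal component, the X-loading is
stripped of its projection on w, X is deflated by the resulting orthogonal
score/loading pair, and the predictive component is computed on the fully
deflated matrix. CV-ANOVA follows Eriksson's formulation with
d1 = (number of model components + 1) and d2 = N - d1 - 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold


@dataclass
class ScaledMatrix:
    """Column-centered/scaled matrix with the transform retained."""

    X: np.ndarray  # samples x retained features
    feature_ids: list[str]
    means: np.ndarray
    scales: np.ndarray
    scaling: str
    dropped: list[str] = field(default_factory=list)  # zero-variance columns

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.means) / self.scales

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.scales + self.means


def scale_matrix(
    X: np.ndarray, scaling: str = "uv", feature_ids: Optional[Sequence[str]] = None
) -> ScaledMatrix:
    """Center columns and scale: ``uv`` by sample SD, ``pareto`` by sqrt(SD),
    ``center_only`` not at all. Zero-variance columns are dropped and listed."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scale_matrix needs a 2-D matrix with >= 2 samples")
    ids = list(feature_ids) if feature_ids is not None else [f"col{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [ids[j] for j in np.flatnonzero(~keep)]
    if not keep.any():
        raise ValueError("all columns have zero variance")
    Xk = X[:, keep]
    means = Xk.mean(axis=0)
    sdk = sd[keep]
    if scaling == "uv":
        scales = sdk
    elif scaling == "pareto":
        scales = np.sqrt(sdk)
    elif scaling == "center_only":
        scales = np.ones_like(sdk)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return ScaledMatrix(
        X=(Xk - means) / scales,
        feature_ids=[ids[j] for j in np.flatnonzero(keep)],
        means=means,
        scales=scales,
        scaling=scaling,
        dropped=dropped,
    )


# -- PCA --------------------------------------------------------------------


@dataclass
class PcaModel:
    scores: np.ndarray  # samples x A
    loadings: np.ndarray  # features x A
    r2x: np.ndarray  # explained variance fraction per component


def fit_pca(scaled: ScaledMatrix, n_components: int) -> PcaModel:
    """PCA by SVD with a deterministic sign convention (the largest-magnitude
    element of each loading vector is made positive)."""
    X = scaled.X
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components exceeds the matrix rank bound")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_ss = float((X**2).sum())
    loadings = Vt[:n_components].T.copy()
    scores = (U[:, :n_components] * s[:n_components]).copy()
    for a in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    r2x = (s[:n_components] ** 2) / total_ss
    return PcaModel(scores=scores, loadings=loadings, r2x=r2x)


# -- OPLS-DA ----------------------------------------------------------------


def code_classes(y: Sequence) -> tuple[np.ndarray, list]:
    """Binary labels -> centered +/-1 dummy vector (classes sorted)."""
    labels = list(y)
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {classes}")
    coded = np.where(np.asarray(labels, dtype=object) == classes[1], 1.0, -1.0)
    return coded, classes


@dataclass
class OplsModel:
    """One predictive + ``n_ortho`` orthogonal components for a binary y."""

    w: np.ndarray  # predictive weights (unit norm)
    p: np.ndarray  # predictive X-loading
    t: np.ndarray  # predictive score
    q: float  # y-loading of the predictive component
    W_o: np.ndarray  # features x n_ortho orthogonal weights (unit norm)
    P_o: np.ndarray  # features x n_ortho orthogonal loadings
    T_o: np.ndarray  # samples x n_ortho orthogonal scores
    y_mean: float
    classes: list
    r2y: float
    ssy_pred: float  # y sum of squares explained by the predictive component
    ssx_ortho: np.ndarray  # X sum of squares captured per orthogonal component

    @property
    def n_ortho(self) -> int:
        return self.W_o.shape[1]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Predictive score of new (already scaled) samples."""
        Xd = np.array(X, dtype=float, copy=True)
        for a in range(self.n_ortho):
            t_o = Xd @ self.W_o[:, a]
            Xd -= np.outer(t_o, self.P_o[:, a])
        return Xd @ self.w

    def predict_y(self, X: np.ndarray) -> np.ndarray:
        return self.predict_scores(X) * self.q + self.y_mean

    def predict_class(self, X: np.ndarray) -> list:
        return [self.classes[1] if v >= 0 else self.classes[0] for v in self.predict_y(X)]


def fit_oplsda(X: np.ndarray, y: Sequence, n_ortho: int = 0) -> OplsModel:
    """Fit OPLS-DA on a scaled matrix and binary class labels.

    ``n_ortho`` is reduced with a warning if the residual matrix runs out of
    y-orthogonal structure before the requested number of components.
    """
    X = np.asarray(X, dtype=float)
    coded, classes = code_classes(y)
    for c, lbl in zip(np.unique(coded), classes):
        if (coded == c).sum() < 2:
            raise ValueError(f"class {lbl!r} has fewer than 2 samples")
    y_mean = float(coded.mean())
    yc = coded - y_mean

    Xd = X.copy()
    W_o, P_o, T_o, ssx_o = [], [], [], []
    for _ in range(n_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            warnings.warn("no y-correlated structure left; stopping orthogonal extraction")
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-10 * np.linalg.norm(p):
            warnings.warn("residual X-loading is collinear with w; reducing n_ortho")
            break
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
        ssx_o.append(float((t_o @ t_o) * (p_o @ p_o)))

    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("y is orthogonal to every X column; no predictive component")
    w /= nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    resid = yc - t * q
    ss_tot = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0

    k = len(W_o)
    d = X.shape[1]
    return OplsModel(
        w=w,
        p=p,
        t=t,
        q=q,
        W_o=np.column_stack(W_o) if k else np.empty((d, 0)),
        P_o=np.column_stack(P_o) if k else np.empty((d, 0)),
        T_o=np.column_stack(T_o) if k else np.empty((X.shape[0], 0)),
        y_mean=y_mean,
        classes=classes,
        r2y=r2y,
        ssy_pred=float((t @ t) * q * q),
        ssx_ortho=np.asarray(ssx_o),
    )


@dataclass
class CvResult:
    q2: float
    press: float
    ss_tot: float
    fold_assignment: np.ndarray
    submodels: list[OplsModel]
    residuals: np.ndarray  # out-of-fold prediction errors of coded y


def cross_validated_q2(
    X: np.ndarray, y: Sequence, n_ortho: int, folds: int = 7, seed: int = 0
) -> CvResult:
    """Q2 = 1 - PRESS / SS_tot under seeded stratified K-fold CV.

    Each fold's model is refit on the training rows only (columns re-centered
    on training means) and predicts the held-out coded responses. Folds are
    clamped so every training split keeps both classes.
    """
    X = np.asarray(X, dtype=float)
    coded, _ = code_classes(y)
    labels = np.asarray([str(v) for v in y])
    min_class = min(np.sum(labels == c) for c in np.unique(labels))
    n_splits = min(folds, int(min_class)) if min_class >= 2 else 2
    if n_splits < folds:
        warnings.warn(f"reducing folds from {folds} to {n_splits} to keep classes in training")
    if n_splits < 2:
        raise ValueError("cross-validation needs >= 2 folds")

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    press = 0.0
    residuals = np.empty(len(labels))
    submodels: list[OplsModel] = []
    y_list = list(y)
    for k, (train, test) in enumerate(skf.split(X, labels)):
        assignment[test] = k
        mu = X[train].mean(axis=0)
        sub = fit_oplsda(X[train] - mu, [y_list[i] for i in train], n_ortho=n_ortho)
        pred = sub.predict_y(X[test] - mu)
        err = coded[test] - pred
        residuals[test] = err
        press += float(err @ err)
        submodels.append(sub)
    ss_tot = float(((coded - coded.mean()) ** 2).sum())
    q2 = 1.0 - press / ss_tot
    return CvResult(
        q2=q2,
        press=press,
        ss_tot=ss_tot,
        fold_assignment=assignment,
        submodels=submodels,
        residuals=residuals,
    )


def select_n_ortho(
    X: np.ndarray, y: Sequence, max_ortho: int = 3, folds: int = 7, seed: int = 0
) -> tuple[int, dict[int, float]]:
    """Forward selection of the orthogonal-component count.

    Returns the smallest count in 0..max_ortho maximizing cross-validated
    Q2, plus the Q2 profile.
    """
    profile: dict[int, float] = {}
    for a in range(max_ortho + 1):
        try:
            profile[a] = cross_validated_q2(X, y, n_ortho=a, folds=folds, seed=seed).q2
        except ValueError:
            break
    best = max(profile, key=lambda a: (profile[a], -a))
    return best, profile


def cv_anova(press: float, ss_tot: float, n_samples: int, n_components: int) -> float:
    """CV-ANOVA p-value on cross-validated predictive residuals.

    F = ((SS_tot - PRESS)/d1) / (PRESS/d2) with d1 = n_components + 1
    (predictive plus orthogonal components plus one) and d2 = N - d1 - 1;
    the p-value is the F distribution's upper tail. A model with no
    predictive ability (PRESS >= SS_tot) yields p = 1.
    """
    d1 = n_components + 1
    d2 = n_samples - d1 - 1
    if d2 <= 0:
        raise ValueError(f"too few samples ({n_samples}) for {n_components} components")
    if press <= 0:
        return 0.0
    f = max((ss_tot - press) / d1, 0.0) / (press / d2)
    return float(stats.f.sf(f, d1, d2))


@dataclass
class PermutationResult:
    n_iter: int
    r2_obs: float
    q2_obs: float
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    p_r2: float
    p_q2: float


def permutation_test(
    X: np.ndarray,
    y: Sequence,
    n_iter: int = 1000,
    seed: int = 0,
    n_ortho: int = 0,
    folds: int = 7,
) -> PermutationResult:
    """Label-permutation null for R2Y and Q2.

    Each iteration permutes y, refits the model and recomputes CV Q2;
    p = (1 + #{perm >= observed}) / (1 + n_iter), so p is bounded below by
    1/(n_iter + 1).
    """
    rng = np.random.default_rng(seed)
    y_list = list(y)
    r2_obs = fit_oplsda(X, y_list, n_ortho=n_ortho).r2y
    q2_obs = cross_validated_q2(X, y_list, n_ortho=n_ortho, folds=folds, seed=seed).q2
    r2_perm = np.empty(n_iter)
    q2_perm = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(len(y_list))
        y_p = [y_list[j] for j in perm]
        try:
            r2_perm[i] = fit_oplsda(X, y_p, n_ortho=n_ortho).r2y
            q2_perm[i] = cross_validated_q2(
                X, y_p, n_ortho=n_ortho, folds=folds, seed=seed + i + 1
            ).q2
        except ValueError:
            r2_perm[i] = np.nan
            q2_perm[i] = np.nan
    ok_r2 = r2_perm[~np.isnan(r2_perm)]
    ok_q2 = q2_perm[~np.isnan(q2_perm)]
    p_r2 = (1 + int((ok_r2 >= r2_obs).sum())) / (1 + len(ok_r2))
    p_q2 = (1 + int((ok_q2 >= q2_obs).sum())) / (1 + len(ok_q2))
    return PermutationResult(
        n_iter=n_iter, r2_obs=r2_obs, q2_obs=q2_obs,
        r2_perm=r2_perm, q2_perm=q2_perm, p_r2=p_r2, p_q2=p_q2,
    )


@dataclass
class ValidationReport:
    r2y: float
    q2: float
    q2_threshold_passed: bool
    cv_anova_p: float
    permutation: PermutationResult
    overall_valid: bool


def validate_model(
    X: np.ndarray,
    y: Sequence,
    n_ortho: int,
    folds: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
    q2_threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[OplsModel, CvResult, ValidationReport]:
    """Fit and validate an OPLS-DA model the way the workflow prescribes."""
    model = fit_oplsda(X, y, n_ortho=n_ortho)
    cv = cross_validated_q2(X, y, n_ortho=n_ortho, folds=folds, seed=seed)
    p_cv = cv_anova(cv.press, cv.ss_tot, X.shape[0], n_components=1 + model.n_ortho)
    perm = permutation_test(
        X, y, n_iter=n_permutations, seed=seed, n_ortho=n_ortho, folds=folds
    )
    q2_ok = cv.q2 > q2_threshold
    report = ValidationReport(
        r2y=model.r2y,
        q2=cv.q2,
        q2_threshold_passed=q2_ok,
        cv_anova_p=p_cv,
        permutation=perm,
        overall_valid=bool(q2_ok and p_cv < alpha and perm.p_q2 < alpha and perm.p_r2 < alpha),
    )
    return model, cv, report
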