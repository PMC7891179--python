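"""Pairwise diagnostic classification of oculomotor feature vectors.

The pipeline follows the published recipe for separating two diagnostic
groups from their oculomotor parameters:

1. z-normalization, x_hat = (x - x_bar) / sigma, with the training mean and
   sample SD stored and re-applied verbatim to held-out or external rows;
2. univariate feature selection — keep parameters whose two-group
   comparison reaches p < 0.001, and drop parameters with any missing
   value across subjects;
3. Fisher-discriminant-ratio ranking, FDR = (mu1 - mu2)^2 / (s1^2 + s2^2)
   (the summed-variance denominator; a subtraction would be sign-indefinite);
4. optionally, a PLS2 projection (NIPALS with iterative deflation) when the
   feature count still exceeds the sample count;
5. a classifier chosen by cross-validated AUC over a candidate grid of
   support-vector machines (linear and RBF) and k-nearest-neighbour
   models (k in {1, 3, 5, 7});
6. a confidence loop: in each of (by default) 1,000 iterations the sample
   is re-split into a stratified 80%/20% train/test partition, the model is
   refit, and ROC AUC plus accuracy are scored on the held-out 20%; the
   report carries the best, worst and mean of both.

Feature selection defaults to running inside each training split (leakage
guard).  ``selection="cohort"`` performs it once on the full sample before
the loop, matching the published procedure in which the per-pair feature
list was fixed before the cross-validation loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "Standardizer",
    "zscore_fit_apply",
    "FDRScore",
    "fdr_scores",
    "PLSModel",
    "pls2_fit",
    "pls2_project",
    "select_training_features",
    "candidate_models",
    "search_models",
    "PipelineConfig",
    "PairClassifier",
    "CVReport",
    "cv_confidence_loop",
    "external_validate",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Column-wise z-normalization with stored (mean, sample SD)."""

    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None
    columns_: tuple[str, ...] | None = None

    def fit(self, x: pd.DataFrame | np.ndarray) -> "Standardizer":
        arr, cols = _as_array(x)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        bad = np.flatnonzero(~(sd > 0))
        if bad.size:
            name = cols[bad[0]] if cols else f"column {bad[0]}"
            raise ValueError(f"constant feature {name!r} cannot be standardized")
        self.mean_, self.sd_, self.columns_ = mean, sd, cols
        return self

    def transform(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("standardizer not fitted")
        arr, cols = _as_array(x)
        if self.columns_ and cols and cols != self.columns_:
            missing = set(self.columns_) - set(cols)
            if missing:
                raise ValueError(f"missing feature {sorted(missing)[0]!r}")
            arr = pd.DataFrame(arr, columns=cols)[list(self.columns_)].to_numpy()
        return (arr - self.mean_) / self.sd_

    def fit_transform(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def _as_array(x) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), tuple(x.columns)
    return np.asarray(x, dtype=float), None


def zscore_fit_apply(
    train: pd.DataFrame | np.ndarray,
    *apply_to: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Standardize training columns; re-apply the stored (mean, SD) to the
    remaining matrices.  Returns the transformed matrices in order."""
    sc = Standardizer().fit(train)
    return tuple([sc.transform(train), *(sc.transform(a) for a in apply_to)])


# ---------------------------------------------------------------------------
# Fisher discriminant ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FDRScore:
    feature: str
    mu1: float
    mu2: float
    var1: float
    var2: float

    @property
    def infinite(self) -> bool:
        return self.var1 + self.var2 == 0 and self.mu1 != self.mu2

    @property
    def score(self) -> float:
        num = (self.mu1 - self.mu2) ** 2
        den = self.var1 + self.var2
        if den == 0:
            return np.inf if num > 0 else 0.0
        return num / den


def fdr_scores(
    x: pd.DataFrame | np.ndarray,
    y: Sequence,
) -> list[FDRScore]:
    """Per-feature Fisher discriminant ratios, ranked descending.

    Both classes must be non-empty; zero variance in both classes with
    distinct means is reported as an infinite score (flagged via
    ``FDRScore.infinite``).
    """
    arr, cols = _as_array(x)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("FDR requires exactly two non-empty classes")
    a, b = arr[y == classes[0]], arr[y == classes[1]]
    out = []
    for j in range(arr.shape[1]):
        name = cols[j] if cols else f"f{j}"
        s = FDRScore(
            feature=name,
            mu1=float(a[:, j].mean()),
            mu2=float(b[:, j].mean()),
            var1=float(a[:, j].var(ddof=1)) if len(a) > 1 else 0.0,
            var2=float(b[:, j].var(ddof=1)) if len(b) > 1 else 0.0,
        )
        if s.infinite:
            log.warning("feature %s has infinite class separation", name)
        out.append(s)
    return sorted(out, key=lambda s: s.score, reverse=True)


# ---------------------------------------------------------------------------
# PLS2 (NIPALS with iterative deflation)
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Scores/loadings of a PLS2 decomposition X = T P' + E, Y = U Q' + F."""

    T: np.ndarray  # X scores, n x p
    U: np.ndarray  # Y scores, n x p
    P: np.ndarray  # X loadings, N x p
    Q: np.ndarray  # Y loadings, M x p
    W: np.ndarray  # X weights, N x p
    E: np.ndarray  # X residual, n x N
    F: np.ndarray  # Y residual (Y - U Q'), n x M
    n_components: int


def pls2_fit(
    x: np.ndarray, y: np.ndarray, n_components: int, tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a PLS2 decomposition by NIPALS with component-wise deflation.

    ``x`` (n x N) and ``y`` (n x M, 2-D) are expected centred/normalized.
    Successive X-score columns are mutually orthogonal and, at
    ``n_components = rank(x)``, the X reconstruction ``T P'`` is exact to
    numerical precision.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    n, nx = x.shape
    if n_components > min(n - 1, nx):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, n_features)="
            f"{min(n - 1, nx)}"
        )
    xd, yd = x.copy(), y.copy()
    T, U, P, Q, W = [], [], [], [], []
    for _ in range(n_components):
        u = yd[:, int(np.argmax(yd.var(axis=0)))].copy()
        if not np.any(u):
            u = np.ones(n)
        t_old = None
        for _ in range(max_iter):
            w = xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = xd @ w
            tt = t @ t
            if tt == 0:
                break
            q = yd.T @ t / tt
            nq = np.linalg.norm(q)
            if nq > 0:
                q = q / nq
            u = yd @ q
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        p_load = xd.T @ t / tt
        b = (u @ t) / tt
        xd = xd - np.outer(t, p_load)
        yd = yd - b * np.outer(t, q)
        T.append(t)
        U.append(u)
        P.append(p_load)
        Q.append(q)
        W.append(w)
    T = np.column_stack(T)
    U = np.column_stack(U)
    P = np.column_stack(P)
    Q = np.column_stack(Q)
    W = np.column_stack(W)
    E = x - T @ P.T
    F = y - U @ Q.T
    return PLSModel(T=T, U=U, P=P, Q=Q, W=W, E=E, F=F, n_components=n_components)


def pls2_project(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    """Project new (already normalized) rows onto the X-score space.

    Uses the rotation W (P' W)^-1; projecting the training X reproduces T.
    """
    rot = model.W @ np.linalg.inv(model.P.T @ model.W)
    return np.asarray(x_new, float) @ rot


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def select_training_features(
    x: pd.DataFrame,
    y: Sequence,
    p_threshold: float = 0.001,
) -> list[str]:
    """Features passing the univariate two-group filter at p < threshold.

    Columns with any missing value are excluded first (parameters
    susceptible to unavailable values never enter the classifier); the
    surviving columns are tested with a two-sample t-test (the two-group
    ANOVA) and returned ranked by Fisher discriminant ratio.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("feature selection requires exactly two classes")
    complete = [c for c in x.columns if not x[c].isna().any()]
    kept = []
    for c in complete:
        a = x.loc[y == classes[0], c].to_numpy(float)
        b = x.loc[y == classes[1], c].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            continue
        _, p = stats.ttest_ind(a, b, equal_var=True)
        if p < p_threshold:
            kept.append(c)
    if not kept:
        raise ValueError(
            f"no feature reaches p < {p_threshold}; relax the threshold"
        )
    ranked = fdr_scores(x[kept], y)
    return [s.feature for s in ranked]


# ---------------------------------------------------------------------------
# Model grid
# ---------------------------------------------------------------------------


def candidate_models(kinds: Sequence[str] = ("svm", "knn")) -> list[tuple[str, object, int]]:
    """The candidate grid: (name, estimator, simplicity rank).

    Lower simplicity rank wins ties (linear kernel before RBF, larger k
    before smaller).
    """
    out: list[tuple[str, object, int]] = []
    if "svm" in kinds:
        out.append(("svm_linear", SVC(kernel="linear", C=1.0), 0))
        out.append(("svm_rbf", SVC(kernel="rbf", C=1.0, gamma="scale"), 1))
    if "knn" in kinds:
        for rank, k in enumerate((7, 5, 3, 1)):
            out.append((f"knn_{k}", KNeighborsClassifier(n_neighbors=k), 2 + rank))
    return out


def _decision_scores(est, x: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return est.decision_function(x)
    return est.predict_proba(x)[:, 1]


def _clone(est):
    from sklearn.base import clone

    return clone(est)


def search_models(
    x: pd.DataFrame,
    y: Sequence,
    seed: int,
    kinds: Sequence[str] = ("svm", "knn"),
    p_threshold: float = 0.001,
    n_folds: int = 5,
) -> tuple[str, object]:
    """Pick the candidate with the best cross-validated AUC.

    Features are selected inside each training fold; ties break toward the
    simpler model.  Deterministic under ``seed``.
    """
    y = np.asarray(y)
    x = x[[c for c in x.columns if not x[c].isna().any()]]
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                         random_state=int(rng.integers(2**31 - 1)))
    results = []
    for name, est, rank in candidate_models(kinds):
        aucs = []
        for tr_idx, te_idx in cv.split(x, y):
            xtr, xte = x.iloc[tr_idx], x.iloc[te_idx]
            ytr, yte = y[tr_idx], y[te_idx]
            if len(np.unique(yte)) < 2:
                continue
            try:
                feats = select_training_features(xtr, ytr, p_threshold)
            except ValueError:
                continue
            sc = Standardizer().fit(xtr[feats])
            model = _clone(est).fit(sc.transform(xtr[feats]), ytr)
            scores = _decision_scores(model, sc.transform(xte[feats]))
            aucs.append(roc_auc_score(yte, scores))
        mean_auc = float(np.mean(aucs)) if aucs else 0.0
        results.append((mean_auc, -rank, name, est))
        log.info("candidate %s: CV AUC %.3f", name, mean_auc)
    results.sort(key=lambda r: (r[0], r[1]), reverse=True)
    best = results[0]
    return best[2], best[3]


# ---------------------------------------------------------------------------
# The confidence loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the pairwise classification pipeline."""

    model: str = "svm_linear"
    selection: str = "split"  # "split" (leakage guard) or "cohort"
    p_threshold: float = 0.001
    use_pls: bool = False
    n_pls_components: int = 2
    iterations: int = 1000
    test_fraction: float = 0.2


@dataclass
class CVReport:
    """Best/worst/mean AUC and accuracy over the confidence loop."""

    pair: str
    algorithm: str
    iterations: int
    seed: int
    best_auc: float
    worst_auc: float
    mean_auc: float
    best_accuracy: float
    worst_accuracy: float
    mean_accuracy: float
    selected_features: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "pair": self.pair,
            "algorithm": self.algorithm,
            "iterations": self.iterations,
            "seed": self.seed,
            "best_auc": self.best_auc,
            "worst_auc": self.worst_auc,
            "mean_auc": self.mean_auc,
            "best_accuracy": self.best_accuracy,
            "worst_accuracy": self.worst_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "selected_features": self.selected_features,
        }


@dataclass
class PairClassifier:
    """A fitted pairwise pipeline (selection + normalization + model)."""

    config: PipelineConfig
    features: list[str]
    scaler: Standardizer
    model: object
    pls: PLSModel | None
    classes: tuple

    def _design(self, x: pd.DataFrame) -> np.ndarray:
        z = self.scaler.transform(x[self.features])
        if self.pls is not None:
            z = pls2_project(self.pls, z)
        return z

    def decision_scores(self, x: pd.DataFrame) -> np.ndarray:
        return _decision_scores(self.model, self._design(x))

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return self.model.predict(self._design(x))


def _estimator(name: str):
    for cand_name, est, _ in candidate_models():
        if cand_name == name:
            return _clone(est)
    raise ValueError(f"unknown model {name!r}")


def fit_pair_classifier(
    x: pd.DataFrame,
    y: Sequence,
    config: PipelineConfig,
    features: Sequence[str] | None = None,
) -> PairClassifier:
    """Fit the full pipeline on a training sample."""
    y = np.asarray(y)
    feats = (
        list(features)
        if features is not None
        else select_training_features(x, y, config.p_threshold)
    )
    scaler = Standardizer().fit(x[feats])
    z = scaler.transform(x[feats])
    pls = None
    if config.use_pls:
        ncomp = min(config.n_pls_components, len(y) - 1, len(feats))
        ybin = (y == np.unique(y)[1]).astype(float)[:, None]
        ybin = (ybin - ybin.mean()) / ybin.std(ddof=1)
        pls = pls2_fit(z, ybin, ncomp)
        z = pls.T
    model = _estimator(config.model).fit(z, y)
    return PairClassifier(
        config=config,
        features=feats,
        scaler=scaler,
        model=model,
        pls=pls,
        classes=tuple(np.unique(y)),
    )


def cv_confidence_loop(
    x: pd.DataFrame,
    y: Sequence,
    config: PipelineConfig,
    seed: int,
    pair: str = "",
) -> CVReport:
    """Stratified 80/20 confidence loop.

    Each iteration re-randomizes a stratified five-way partition (four
    subsets train, one subset tests), refits the pipeline on the 80% and
    scores ROC AUC and accuracy on the 20%.  Requires >= 5 subjects per
    class.  With ``selection="cohort"`` the feature list is fixed once on
    the full sample before the loop.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("confidence loop requires exactly two classes")
    if counts.min() < 5:
        raise ValueError("need >= 5 subjects per class to stratify 80/20")
    # parameters with unavailable values anywhere in the cohort never enter
    # the classifier (availability is not label-dependent: no leakage)
    x = x[[c for c in x.columns if not x[c].isna().any()]]
    rng = np.random.default_rng(seed)
    cohort_feats: list[str] | None = None
    if config.selection == "cohort":
        cohort_feats = select_training_features(x, y, config.p_threshold)
    aucs, accs = [], []
    splitter = StratifiedShuffleSplit(
        n_splits=config.iterations,
        test_size=config.test_fraction,
        random_state=int(rng.integers(2**31 - 1)),
    )
    for tr_idx, te_idx in splitter.split(x, y):
        xtr, xte = x.iloc[tr_idx], x.iloc[te_idx]
        ytr, yte = y[tr_idx], y[te_idx]
        try:
            clf = fit_pair_classifier(xtr, ytr, config, features=cohort_feats)
        except ValueError as exc:
            log.warning("iteration skipped: %s", exc)
            continue
        scores = clf.decision_scores(xte)
        pos = clf.classes[1]
        aucs.append(roc_auc_score((yte == pos).astype(int), scores))
        accs.append(accuracy_score(yte, clf.predict(xte)))
    if not aucs:
        raise ValueError("no successful iterations")
    return CVReport(
        pair=pair,
        algorithm=config.model,
        iterations=len(aucs),
        seed=seed,
        best_auc=float(np.max(aucs)),
        worst_auc=float(np.min(aucs)),
        mean_auc=float(np.mean(aucs)),
        best_accuracy=float(np.max(accs)),
        worst_accuracy=float(np.min(accs)),
        mean_accuracy=float(np.mean(accs)),
        selected_features=cohort_feats or [],
    )


def external_validate(
    clf: PairClassifier,
    x_external: pd.DataFrame,
    y_external: Sequence,
) -> dict:
    """Apply a fitted pipeline to an external cohort without refitting.

    External rows are transformed with the stored training (mean, SD).
    Returns AUC, per-subject calls and confusion counts.
    """
    missing = [f for f in clf.features if f not in x_external.columns]
    if missing:
        raise ValueError(f"missing feature {missing[0]!r} in external cohort")
    y_external = np.asarray(y_external)
    scores = clf.decision_scores(x_external)
    calls = clf.predict(x_external)
    pos = clf.classes[1]
    auc = (
        float(roc_auc_score((y_external == pos).astype(int), scores))
        if len(np.unique(y_external)) == 2
        else np.nan
    )
    tp = int(np.sum((calls == pos) & (y_external == pos)))
    tn = int(np.sum((calls != pos) & (y_external != pos)))
    fp = int(np.sum((calls == pos) & (y_external != pos)))
    fn = int(np.sum((calls != pos) & (y_external == pos)))
    return {
        "auc": auc,
        "calls": list(calls),
        "accuracy": float(accuracy_score(y_external, calls)),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
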