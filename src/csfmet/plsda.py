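"""Two-class PLS-DA with VIP scoring and repeated cross-validation.

The model is fit by the iterative partial-least-squares algorithm on
autoscaled data with the class coded +/-1 and centered. Model quality is
summarized by R2Y (training), Q2 (inner stratified cross-validation) and
label-permutation p-values; biomarker stability by per-variable VIP means
with normal-approximation confidence intervals and fold-level AUROCs under
repeated stratified k-fold cross-validation with vertically averaged ROC
curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

ROC_GRID = np.linspace(0.0, 1.0, 101)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return X, [f"x{j}" for j in range(X.shape[1])]


def _code_labels(y, positive: str | None = None) -> tuple[np.ndarray, dict]:
    labels = pd.Series(y).astype(str)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if positive is None:
        positive = classes[1]
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among {classes}")
    negative = classes[0] if classes[1] == positive else classes[1]
    coding = {positive: 1.0, negative: -1.0}
    coded = labels.map(coding).to_numpy(dtype=float)
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    return coded, coding


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model (single centered +/-1 response)."""

    n_components: int
    weights: np.ndarray          # W, p x A, unit-norm columns
    x_loadings: np.ndarray       # P, p x A
    y_loadings: np.ndarray       # c, A
    scores: np.ndarray           # T, n x A
    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    class_coding: dict[str, float]
    variables: list[str]
    r2y: float
    q2: float | None = None
    r2_perm_p: float | None = None
    q2_perm_p: float | None = None

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients for scaled X predicting centered y."""
        w, p, c = self.weights, self.x_loadings, self.y_loadings
        return w @ np.linalg.solve(p.T @ w, np.eye(self.n_components)) @ c

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_means) / self.x_sds

    def predict_score(self, X) -> np.ndarray:
        """Continuous class score (predicted coded y) for new samples."""
        Xm, names = _as_matrix(X)
        Xm = self._select(Xm, names)
        return self.y_mean + self._scale(Xm) @ self.coefficients

    def _select(self, Xm: np.ndarray, names: list[str]) -> np.ndarray:
        if names == self.variables:
            return Xm
        idx = {n: j for j, n in enumerate(names)}
        missing = [v for v in self.variables if v not in idx]
        if missing:
            raise ValueError(f"missing variables: {missing[:10]}")
        return Xm[:, [idx[v] for v in self.variables]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_means": self.x_means.tolist(),
            "x_sds": self.x_sds.tolist(),
            "y_mean": self.y_mean,
            "class_coding": self.class_coding,
            "variables": self.variables,
            "r2y": self.r2y,
            "q2": self.q2,
            "r2_perm_p": self.r2_perm_p,
            "q2_perm_p": self.q2_perm_p,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def fit_plsda(
    X,
    y,
    n_components: int | None = None,
    positive: str | None = None,
    max_components: int = 10,
    seed: int = 0,
) -> PLSDAModel:
    """Fit a two-class PLS-DA model on autoscaled data.

    When ``n_components`` is None the count is chosen automatically: add
    components while inner 7-fold Q2 improves by at least 0.01 (min 1,
    max ``max_components``).
    """
    Xm, names = _as_matrix(X)
    coded, coding = _code_labels(y, positive)
    if Xm.shape[0] != len(coded):
        raise ValueError("X and y length mismatch")

    sds = Xm.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance variables",
                      stacklevel=2)
        Xm = Xm[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        sds = sds[keep]
    if Xm.shape[1] < 1:
        raise ValueError("no variables with nonzero variance")

    if n_components is None:
        n_components = _auto_components(Xm, coded, names, coding, max_components, seed)

    means = Xm.mean(axis=0)
    Xs = (Xm - means) / sds
    y_mean = coded.mean()
    yc = coded - y_mean

    W, P, C, T = _nipals(Xs, yc, n_components)
    A = W.shape[1]
    if A < n_components:
        warnings.warn(f"component count truncated to {A} (rank limit)", stacklevel=2)
    y_hat = T @ C
    tss = float(yc @ yc)
    r2y = 1.0 - float((yc - y_hat) @ (yc - y_hat)) / tss if tss > 0 else 0.0
    return PLSDAModel(
        n_components=A, weights=W, x_loadings=P, y_loadings=C, scores=T,
        x_means=means, x_sds=sds, y_mean=float(y_mean), class_coding=coding,
        variables=names, r2y=r2y,
    )


def _nipals(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """Single-response partial least squares component extraction."""
    Xa = Xs.copy()
    ya = yc.copy()
    ws, ps, cs, ts = [], [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w = w / norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = Xa.T @ t / tt
        c = float(ya @ t / tt)
        Xa = Xa - np.outer(t, p)
        ya = ya - c * t
        ws.append(w)
        ps.append(p)
        cs.append(c)
        ts.append(t)
    if not ws:
        raise ValueError("no PLS component could be extracted (X orthogonal or constant)")
    return (np.column_stack(ws), np.column_stack(ps), np.array(cs), np.column_stack(ts))


def _auto_components(Xm, coded, names, coding, max_components: int, seed: int) -> int:
    labels = np.where(coded > 0, "pos", "neg")
    best_a, best_q2 = 1, -np.inf
    limit = min(max_components, Xm.shape[0] - 1, Xm.shape[1])
    for a in range(1, max(limit, 1) + 1):
        q = q2(Xm, labels, n_components=a, seed=seed)
        if q > best_q2 + 0.01:
            best_a, best_q2 = a, q
        else:
            break
    return best_a


def vip(model: PLSDAModel) -> pd.Series:
    """Variable Importance in the Projection.

    VIP_j = sqrt( p * sum_a[ SSY_a * (w_aj / ||w_a||)^2 ] / sum_a SSY_a )
    with SSY_a = c_a^2 * t_a' t_a, the y-variance captured by component a.
    """
    W, C, T = model.weights, model.y_loadings, model.scores
    p = W.shape[0]
    ssy = C ** 2 * (T ** 2).sum(axis=0)
    wnorm2 = (W ** 2).sum(axis=0)
    contrib = (W ** 2 / wnorm2) @ ssy
    v = np.sqrt(p * contrib / ssy.sum())
    return pd.Series(v, index=model.variables, name="vip")


def auroc(scores, labels, positive=None) -> float:
    """AUROC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    lab = pd.Series(labels).astype(str)
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    pos = positive if positive is not None else classes[1]
    is_pos = (lab == str(pos)).to_numpy()
    n1, n0 = int(is_pos.sum()), int((~is_pos).sum())
    ranks = stats.rankdata(s, method="average")
    u = ranks[is_pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def q2(
    X, y, n_components: int = 2, n_inner_folds: int = 7,
    seed: int = 0, positive: str | None = None,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/TSS of the coded class response.

    Models are refit per fold with training-fold scaling; folds are
    stratified (shuffled, seeded)."""
    Xm, names = _as_matrix(X)
    coded, coding = _code_labels(y, positive)
    counts = pd.Series(y).value_counts()
    folds = int(min(n_inner_folds, counts.min()))
    if folds < 2:
        raise ValueError("each class needs >= 2 samples for Q2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    Xdf = pd.DataFrame(Xm, columns=names)
    labels = pd.Series(y).astype(str).to_numpy()
    pos = [k for k, v in coding.items() if v > 0][0]
    for train, test in skf.split(Xm, labels):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_plsda(Xdf.iloc[train], labels[train],
                          n_components=n_components, positive=pos)
        pred = m.predict_score(Xdf.iloc[test])
        press += float(((coded[test] - pred) ** 2).sum())
    tss = float(((coded - coded.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_test(
    X, y, n_perm: int = 100, n_components: int = 2,
    seed: int = 0, positive: str | None = None,
) -> tuple[float, float]:
    """Label-permutation p-values for R2Y and Q2.

    p = (1 + #{permuted metric >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = pd.Series(y).astype(str).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs_model = fit_plsda(X, labels, n_components=n_components, positive=positive)
    obs_r2 = obs_model.r2y
    obs_q2 = q2(X, labels, n_components=n_components, seed=seed, positive=positive)
    ge_r2 = ge_q2 = 0
    for i in range(n_perm):
        perm = rng.permutation(labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_plsda(X, perm, n_components=n_components, positive=positive)
        if m.r2y >= obs_r2:
            ge_r2 += 1
        if q2(X, perm, n_components=n_components, seed=seed + i + 1,
              positive=positive) >= obs_q2:
            ge_q2 += 1
    return (1 + ge_r2) / (n_perm + 1), (1 + ge_q2) / (n_perm + 1)


@dataclass
class CVSummary:
    """Aggregate of all fold-models from repeated stratified k-fold CV."""

    vip_mean: pd.Series
    vip_ci: pd.DataFrame            # columns: lower, upper
    aurocs: np.ndarray              # one per fold-model
    auroc_mean: float
    auroc_sd: float
    roc_grid: np.ndarray            # 1 - specificity grid
    roc_mean: np.ndarray            # mean sensitivity
    roc_sem: np.ndarray             # SEM of sensitivity
    n_models: int
    holdout_counts: pd.Series       # times each sample was held out
    fold_assignments: list[tuple[int, int, list[int]]] = field(default_factory=list)


def repeated_cv(
    X, y, k: int = 5, repeats: int = 10, seed: int = 0,
    n_components: int | None = None, positive: str | None = None,
) -> CVSummary:
    """Repeated stratified k-fold cross-validation of the PLS-DA model.

    For every fold a model is fit on the remaining k-1 folds; its VIP vector,
    held-out AUROC and ROC curve are collected. VIP confidence intervals use
    the normal approximation over the k*repeats fold-models, ROC curves are
    vertically averaged on a fixed 101-point 1-specificity grid.
    """
    Xm, names = _as_matrix(X)
    labels = pd.Series(y).astype(str).to_numpy()
    counts = pd.Series(labels).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k")
    if n_components is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_components = fit_plsda(Xm, labels, positive=positive, seed=seed).n_components
    Xdf = pd.DataFrame(Xm, columns=names)
    classes = sorted(set(labels))
    pos = positive if positive is not None else classes[1]

    rskf = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    vips, rocs, aucs = [], [], []
    holdout = np.zeros(len(labels), dtype=int)
    assignments = []
    for fold_no, (train, test) in enumerate(rskf.split(Xm, labels)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_plsda(Xdf.iloc[train], labels[train],
                          n_components=n_components, positive=pos)
        v = vip(m).reindex(names)
        vips.append(v.to_numpy())
        pred = m.predict_score(Xdf.iloc[test])
        aucs.append(auroc(pred, labels[test], positive=pos))
        rocs.append(_roc_on_grid(pred, labels[test], pos))
        holdout[test] += 1
        assignments.append((fold_no // k, fold_no % k, [int(i) for i in test]))

    vmat = np.vstack(vips)
    vmean = vmat.mean(axis=0)
    sem = vmat.std(axis=0, ddof=1) / np.sqrt(vmat.shape[0]) if vmat.shape[0] > 1 \
        else np.zeros(vmat.shape[1])
    rmat = np.vstack(rocs)
    aucs = np.asarray(aucs)
    return CVSummary(
        vip_mean=pd.Series(vmean, index=names, name="vip_mean"),
        vip_ci=pd.DataFrame({"lower": vmean - 1.96 * sem, "upper": vmean + 1.96 * sem},
                            index=names),
        aurocs=aucs,
        auroc_mean=float(aucs.mean()),
        auroc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        roc_grid=ROC_GRID.copy(),
        roc_mean=rmat.mean(axis=0),
        roc_sem=(rmat.std(axis=0, ddof=1) / np.sqrt(rmat.shape[0])
                 if rmat.shape[0] > 1 else np.zeros(rmat.shape[1])),
        n_models=vmat.shape[0],
        holdout_counts=pd.Series(holdout),
        fold_assignments=assignments,
    )


def _roc_on_grid(scores: np.ndarray, labels: np.ndarray, positive: str) -> np.ndarray:
    """Sensitivity evaluated on the fixed 1-specificity grid."""
    from sklearn.metrics import roc_curve

    y_bin = (labels == positive).astype(int)
    fpr, tpr, _ = roc_curve(y_bin, scores)
    return np.interp(ROC_GRID, fpr, tpr)


def project(model: PLSDAModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Project held-out samples into a fitted model's score space.

    Returns (scores ``t_new = X_scaled W (P'W)^-1``, predicted class score).
    Never refits."""
    Xm, names = _as_matrix(X_new)
    Xm = model._select(Xm, names)
    Xs = model._scale(Xm)
    rot = model.weights @ np.linalg.solve(
        model.x_loadings.T @ model.weights, np.eye(model.n_components))
    t_new = Xs @ rot
    y_pred = model.y_mean + Xs @ model.coefficients
    return t_new, y_pred


def decision_threshold(model: PLSDAModel, X, y) -> float:
    """Midpoint of the class-mean predicted scores on training data."""
    pred = model.predict_score(X)
    lab = pd.Series(y).astype(str).to_numpy()
    pos = [k for k, v in model.class_coding.items() if v > 0][0]
    return float((pred[lab == pos].mean() + pred[lab != pos].mean()) / 2.0)
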