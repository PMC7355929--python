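"""Model validation: fit statistics, ROC curves, permutation testing, and
score-space outlier diagnostics.

Definitions (dummy-response Y is the one-hot class matrix):

* R2X  — cumulative fraction of X variance captured by the score/loading
  reconstruction.
* R2Y  — 1 - SS(Y - Yhat_train) / SS(Y centered) on the training set.
* Q2   — 1 - PRESS / SS over stratified k-fold cross-validation.
* RMSEE / RMSEP — root mean squared dummy residual on the training / test
  set ("estimation" vs "prediction").
* ROC  — one-vs-rest threshold sweep on class probabilities, points stored
  as (100 - specificity, sensitivity), AUC by the trapezoid rule.
* Permutation test — class labels permuted uniformly; the model is refit
  and cross-validated per permutation; empirical p-value uses the add-one
  estimator (1 + #{perm Q2 >= observed}) / (n_perm + 1).
* Hotelling's T2 — sum of squared scores normalized by training score
  variances, 95% limit A(n-1)/(n-A) F_0.95(A, n-A).
* Q residual — squared reconstruction error orthogonal to the model plane,
  95% limit by the Jackson-Mudholkar approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from oliveauth import chemometrics as chem
from oliveauth.chemometrics import PLSDAModel
from oliveauth.feature_table import FeatureTable
from oliveauth.preprocessing import ScalingParams, apply_scaling_matrix

__all__ = [
    "ModelMetrics",
    "ROCCurve",
    "PermutationResult",
    "OutlierDiagnostics",
    "compute_metrics",
    "roc_curves",
    "permutation_test",
    "outlier_diagnostics",
    "classify_suspects",
]


@dataclass
class ModelMetrics:
    r2x: float
    r2y: float
    q2: float
    rmsee: float
    rmsep: float
    error_train: float
    error_cv: float
    error_test: float
    sensitivity: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)
    confusion_train: np.ndarray | None = None
    confusion_test: np.ndarray | None = None


def _confusion(labels: np.ndarray, assigned: np.ndarray,
               classes: list[str]) -> np.ndarray:
    idx = {c: k for k, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, a in zip(labels, assigned):
        cm[idx[t], idx[a]] += 1
    return cm


def _sens_spec(cm: np.ndarray, classes: list[str]
               ) -> tuple[dict[str, float], dict[str, float]]:
    sens, spec = {}, {}
    total = cm.sum()
    for k, cls in enumerate(classes):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens[cls] = tp / (tp + fn) if tp + fn else np.nan
        spec[cls] = tn / (tn + fp) if tn + fp else np.nan
    return sens, spec


def compute_metrics(
    model: PLSDAModel,
    x_train: np.ndarray,
    y_train,
    x_test: np.ndarray,
    y_test,
    cv_folds: int = 5,
    seed: int = 0,
) -> ModelMetrics:
    """Full fit/prediction statistics for a fitted PLS-DA model."""
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    classes = model.classes
    yd_train = _one_hot(y_train, classes)
    yd_test = _one_hot(y_test, classes)

    yhat_tr, assign_tr, _ = chem.predict(model, x_train)
    yhat_te, assign_te, _ = chem.predict(model, x_test)
    rmsee = float(np.sqrt(np.mean((yd_train - yhat_tr) ** 2)))
    rmsep = float(np.sqrt(np.mean((yd_test - yhat_te) ** 2)))

    ss_y = float(((yd_train - yd_train.mean(axis=0)) ** 2).sum())
    r2y = 1.0 - float(((yd_train - yhat_tr) ** 2).sum()) / ss_y

    yhat_cv, assign_cv = chem.cv_predictions(
        x_train, y_train, model.n_lv, k=cv_folds, seed=seed, classes=classes
    )
    press = float(((yd_train - yhat_cv) ** 2).sum())
    q2 = 1.0 - press / ss_y

    cm_train = _confusion(y_train, assign_tr, classes)
    cm_test = _confusion(y_test, assign_te, classes)
    sens, spec = _sens_spec(cm_test, classes)
    return ModelMetrics(
        r2x=model.r2x,
        r2y=r2y,
        q2=q2,
        rmsee=rmsee,
        rmsep=rmsep,
        error_train=float(np.mean(assign_tr != y_train)),
        error_cv=float(np.mean(assign_cv != y_train)),
        error_test=float(np.mean(assign_te != y_test)),
        sensitivity=sens,
        specificity=spec,
        confusion_train=cm_train,
        confusion_test=cm_test,
    )


def _one_hot(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    y = np.zeros((len(labels), len(classes)))
    idx = {c: k for k, c in enumerate(classes)}
    for i, lab in enumerate(labels):
        y[i, idx[lab]] = 1.0
    return y


@dataclass
class ROCCurve:
    """One-vs-rest ROC for a class: (100 - specificity, sensitivity) points."""

    class_label: str
    points: np.ndarray  # k x 2
    auc: float


def roc_curves(proba: np.ndarray, labels, classes: list[str] | None = None
               ) -> list[ROCCurve]:
    """One-vs-rest ROC per class from class-probability rows."""
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if classes is None:
        classes = sorted(set(labels))
    curves = []
    for k, cls in enumerate(classes):
        pos = labels == cls
        if not pos.any():
            raise ValueError(f"class {cls!r} absent from labels")
        score = proba[:, k]
        thresholds = np.concatenate(([np.inf], np.unique(score)[::-1], [-np.inf]))
        tpr, fpr = [], []
        n_pos, n_neg = pos.sum(), (~pos).sum()
        for thr in thresholds:
            called = score >= thr
            tpr.append((called & pos).sum() / n_pos)
            fpr.append((called & ~pos).sum() / n_neg if n_neg else 0.0)
        tpr_arr, fpr_arr = np.array(tpr), np.array(fpr)
        auc = float(np.trapezoid(tpr_arr, fpr_arr))
        points = np.column_stack([100.0 * fpr_arr, 100.0 * tpr_arr])
        curves.append(ROCCurve(cls, points, auc))
    return curves


@dataclass
class PermutationResult:
    n_perm: int
    observed_q2: float
    observed_r2y: float
    permuted_q2: np.ndarray
    permuted_r2y: np.ndarray
    p_value: float


def _fit_q2_r2y(x: np.ndarray, labels: np.ndarray, n_lv: int,
                cv_folds: int, seed: int) -> tuple[float, float]:
    classes = sorted(set(labels))
    model = chem.fit_plsda(x, labels, n_lv, classes=classes)
    yd = _one_hot(labels, classes)
    yhat, _, _ = chem.predict(model, x)
    ss = float(((yd - yd.mean(axis=0)) ** 2).sum())
    r2y = 1.0 - float(((yd - yhat) ** 2).sum()) / ss
    yhat_cv, _ = chem.cv_predictions(x, labels, n_lv, k=cv_folds,
                                     seed=seed, classes=classes)
    q2 = 1.0 - float(((yd - yhat_cv) ** 2).sum()) / ss
    return q2, r2y


def permutation_test(
    x: np.ndarray,
    labels,
    n_perm: int = 20,
    seed: int = 0,
    n_lv: int = 3,
    cv_folds: int = 5,
) -> PermutationResult:
    """Label-permutation overfitting check on Q2 and R2Y."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    obs_q2, obs_r2y = _fit_q2_r2y(x, labels, n_lv, cv_folds, seed)
    q2s = np.empty(n_perm)
    r2ys = np.empty(n_perm)
    for b in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        while len(set(perm)) < 2:  # guard against degenerate shuffles
            perm = labels[rng.permutation(len(labels))]
        q2s[b], r2ys[b] = _fit_q2_r2y(x, perm, n_lv, cv_folds, seed)
    p = (1 + int(np.sum(q2s >= obs_q2))) / (n_perm + 1)
    return PermutationResult(n_perm, obs_q2, obs_r2y, q2s, r2ys, p)


@dataclass
class OutlierDiagnostics:
    sample_ids: list[str] | None
    hotelling_t2: np.ndarray
    q_residual: np.ndarray
    t2_limit_95: float
    q_limit_95: float

    def outliers(self) -> np.ndarray:
        """Mask of samples exceeding both 95% limits."""
        return (self.hotelling_t2 > self.t2_limit_95) & (
            self.q_residual > self.q_limit_95
        )


def outlier_diagnostics(
    model: PLSDAModel,
    x: np.ndarray,
    x_train: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> OutlierDiagnostics:
    """Hotelling's T2 and Q residuals for the rows of ``x``.

    Score variances and residual eigenvalues come from the training data
    (``x_train``; defaults to ``x``).  The T2 limit uses the F-distribution
    scaling A(n-1)/(n-A) F(A, n-A); the Q limit uses Jackson-Mudholkar.
    """
    x = np.asarray(x, dtype=float)
    t = chem.scores(model, x)
    n_train, a = model.t.shape
    if a >= n_train:
        raise ValueError("latent-variable count must be below training size")
    var_t = model.t.var(axis=0, ddof=1)
    t2 = ((t ** 2) / var_t).sum(axis=1)
    resid = (x - model.x_mean) - t @ model.p.T
    q = (resid ** 2).sum(axis=1)

    f_crit = stats.f.ppf(1 - alpha, a, n_train - a)
    t2_limit = a * (n_train - 1) / (n_train - a) * f_crit

    train = np.asarray(x_train, dtype=float) if x_train is not None else x
    t_train = chem.scores(model, train)
    resid_train = (train - model.x_mean) - t_train @ model.p.T
    sv = np.linalg.svd(resid_train, compute_uv=False)
    lam = (sv ** 2) / max(len(train) - 1, 1)
    lam = lam[lam > 1e-12 * lam.max()] if lam.size else lam
    q_limit = _jackson_mudholkar(lam, alpha)
    return OutlierDiagnostics(sample_ids, t2, q, float(t2_limit), float(q_limit))


def _jackson_mudholkar(lam: np.ndarray, alpha: float) -> float:
    if lam.size == 0:
        return 0.0
    th1, th2, th3 = lam.sum(), (lam ** 2).sum(), (lam ** 3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2 ** 2)
    if h0 <= 0:
        h0 = 1e-3
    z = stats.norm.ppf(1 - alpha)
    term = (
        z * np.sqrt(2.0 * th2 * h0 ** 2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1 ** 2
    )
    return float(th1 * term ** (1.0 / h0)) if term > 0 else 0.0


@dataclass
class SuspectResult:
    sample_ids: list[str]
    assigned: np.ndarray
    proba: np.ndarray
    diagnostics: OutlierDiagnostics


def classify_suspects(
    model: PLSDAModel,
    scaling_params: ScalingParams,
    suspect_table: FeatureTable,
    x_train: np.ndarray | None = None,
) -> SuspectResult:
    """Scale suspect rows with the training parameters, predict classes,
    and flag samples outside the 95% T2/Q limits."""
    x = apply_scaling_matrix(suspect_table.intensities, scaling_params)
    _, assigned, proba = chem.predict(model, x)
    diag = outlier_diagnostics(
        model, x, x_train=x_train,
        sample_ids=list(suspect_table.samples["sample_id"]),
    )
    return SuspectResult(
        list(suspect_table.samples["sample_id"]), assigned, proba, diag
    )
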