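"""PCA, PLS-DA (NIPALS PLS2), VIP scores, and pairwise OPLS-DA markers.

PLS-DA is PLS2 regression of the feature matrix onto a one-hot class
dummy matrix.  Components are extracted by the classical NIPALS iteration
(convergence tolerance 1e-10, at most 500 iterations per component) with
deflation of both blocks after each component.  The latent-variable count
is chosen by stratified k-fold cross-validated misclassification error
(smallest count attaining the minimum).

Variable importance in projection (VIP) for feature j over A components::

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

where SSY_a is the reduction in dummy-response sum of squares achieved by
component a and p the feature count; squared VIPs average to 1 by
construction.  Markers are the features whose VIP exceeds the cutoff
(default 0.83, strict inequality).

Pairwise class contrasts use an orthogonal-signal-correction step (one
orthogonal component removed) followed by a single predictive PLS
component, mirroring one-vs-one OPLS-DA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PCAResult",
    "PLSDAModel",
    "VIPRecord",
    "fit_pca",
    "fit_plsda",
    "predict",
    "select_n_lv",
    "stratified_folds",
    "vip",
    "vip_records",
    "pairwise_oplsda_vip",
    "select_markers",
]

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


@dataclass
class PCAResult:
    scores: np.ndarray          # n x A
    loadings: np.ndarray        # p x A
    explained: np.ndarray       # variance fractions, non-increasing
    mean: np.ndarray


def fit_pca(x: np.ndarray, n_components: int) -> PCAResult:
    """Principal components of the mean-centered matrix via SVD."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s ** 2).sum())
    explained = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAResult(
        scores=u[:, :n_components] * s[:n_components],
        loadings=vt[:n_components].T,
        explained=explained,
        mean=mean,
    )


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 classifier on one-hot class dummies."""

    n_lv: int
    classes: list[str]                  # dummy-column order
    x_mean: np.ndarray
    y_mean: np.ndarray
    w: np.ndarray                       # x-weights, p x A
    p: np.ndarray                       # x-loadings, p x A
    t: np.ndarray                       # x-scores (training), n x A
    c: np.ndarray                       # y-loadings, m x A
    ssy: np.ndarray                     # Y sum-of-squares explained per LV
    ssx: np.ndarray                     # X sum-of-squares explained per LV
    ssx_total: float
    ssy_total: float
    training_ids: list[str] | None = None
    coef: np.ndarray = field(init=False)  # p x m regression matrix

    def __post_init__(self) -> None:
        # B = W (P'W)^-1 C'
        pw = self.p.T @ self.w
        self.coef = self.w @ np.linalg.solve(pw, self.c.T)

    @property
    def r2x(self) -> float:
        return float(self.ssx.sum() / self.ssx_total) if self.ssx_total else 0.0

    @property
    def r2y(self) -> float:
        return float(self.ssy.sum() / self.ssy_total) if self.ssy_total else 0.0


def _dummy(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    y = np.zeros((len(labels), len(classes)))
    index = {c: k for k, c in enumerate(classes)}
    for i, lab in enumerate(labels):
        y[i, index[lab]] = 1.0
    return y


def fit_plsda(
    x: np.ndarray,
    labels,
    n_lv: int,
    classes: list[str] | None = None,
    training_ids: list[str] | None = None,
) -> PLSDAModel:
    """Fit a PLS2 discriminant model with ``n_lv`` latent variables.

    ``x`` is the already-scaled feature matrix; labels are class names.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    if n_lv > min(x.shape):
        raise ValueError("n_lv exceeds matrix rank bound")
    y = _dummy(labels, classes)
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    e = x - x_mean
    f = y - y_mean
    ssx_total = float((e ** 2).sum())
    ssy_total = float((f ** 2).sum())
    n, p = x.shape
    m = y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    C = np.zeros((m, n_lv))
    ssy = np.zeros(n_lv)
    ssx = np.zeros(n_lv)
    n_extracted = n_lv
    for a in range(n_lv):
        # stop early once the dummy response is exhausted (residual Y
        # variance negligible): further components are 0/0-degenerate
        if (f ** 2).sum() <= 1e-12 * max(ssy_total, 1.0):
            n_extracted = a
            break
        u = f[:, int(np.argmax(f.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(NIPALS_MAX_ITER):
            w = e.T @ u / (u @ u)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"degenerate component {a + 1}: zero weights")
            w /= norm
            t = e @ w
            c = f.T @ t / (t @ t)
            u = f @ c / (c @ c)
            if np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        pv = e.T @ t / (t @ t)
        e = e - np.outer(t, pv)
        f = f - np.outer(t, c)
        W[:, a], P[:, a], T[:, a], C[:, a] = w, pv, t, c
        ssy[a] = (t @ t) * (c @ c)   # reduction in Y sum of squares
        ssx[a] = (t @ t) * (pv @ pv)
    a_eff = n_extracted
    if a_eff == 0:
        raise ValueError("response carries no variance to model")
    return PLSDAModel(
        n_lv=a_eff, classes=list(classes), x_mean=x_mean, y_mean=y_mean,
        w=W[:, :a_eff], p=P[:, :a_eff], t=T[:, :a_eff], c=C[:, :a_eff],
        ssy=ssy[:a_eff], ssx=ssx[:a_eff],
        ssx_total=ssx_total, ssy_total=ssy_total, training_ids=training_ids,
    )


def predict(
    model: PLSDAModel, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict dummy responses, class assignments, and class probabilities.

    Assignment is the argmax dummy column (first class in model order on
    ties); probabilities are the softmax of the predicted dummy values, so
    each row sums to 1.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != len(model.x_mean):
        raise ValueError("feature count does not match the fitted model")
    yhat = (x - model.x_mean) @ model.coef + model.y_mean
    z = yhat - yhat.max(axis=1, keepdims=True)
    proba = np.exp(z)
    proba /= proba.sum(axis=1, keepdims=True)
    assign = np.array([model.classes[k] for k in np.argmax(yhat, axis=1)])
    return yhat, assign, proba


def scores(model: PLSDAModel, x: np.ndarray) -> np.ndarray:
    """Project new rows onto the model's latent variables (n x A)."""
    e = np.asarray(x, dtype=float) - model.x_mean
    t = np.zeros((e.shape[0], model.n_lv))
    for a in range(model.n_lv):
        t[:, a] = e @ model.w[:, a]
        e = e - np.outer(t[:, a], model.p[:, a])
    return t


def stratified_folds(
    labels: np.ndarray, k: int, seed: int = 0
) -> list[np.ndarray]:
    """Class-stratified fold index arrays (shuffled per class, dealt
    round-robin); every class must have at least k members."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has fewer than {k} members")
        idx = idx[rng.permutation(len(idx))]
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def cv_predictions(
    x: np.ndarray, labels, n_lv: int, k: int = 5, seed: int = 0,
    classes: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold dummy predictions and class assignments under k-fold CV."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(set(labels))
    yhat = np.zeros((len(labels), len(classes)))
    assign = np.empty(len(labels), dtype=object)
    for fold in stratified_folds(labels, k, seed):
        mask = np.ones(len(labels), dtype=bool)
        mask[fold] = False
        model = fit_plsda(x[mask], labels[mask], n_lv, classes=classes)
        yh, asg, _ = predict(model, x[fold])
        yhat[fold] = yh
        assign[fold] = asg
    return yhat, assign.astype(str)


def select_n_lv(
    x: np.ndarray, labels, k: int = 5, max_lv: int = 10, seed: int = 0
) -> tuple[int, np.ndarray]:
    """Smallest latent-variable count minimizing stratified k-fold CV
    misclassification error; returns (n_lv, per-count error array)."""
    labels = np.asarray(labels)
    max_lv = min(max_lv, min(np.asarray(x).shape) - 1)
    errors = np.empty(max_lv)
    for a in range(1, max_lv + 1):
        _, assign = cv_predictions(x, labels, a, k=k, seed=seed)
        errors[a - 1] = float(np.mean(assign != labels))
    best = int(np.argmin(errors)) + 1  # argmin takes the smallest A on ties
    return best, errors


def vip(model: PLSDAModel) -> np.ndarray:
    """Overall VIP score per feature; squared values average to 1."""
    w_norm = model.w / np.linalg.norm(model.w, axis=0, keepdims=True)
    p = model.w.shape[0]
    weights = model.ssy / model.ssy.sum()
    return np.sqrt(p * (w_norm ** 2) @ weights)


@dataclass
class VIPRecord:
    """Overall and pairwise VIP values for one feature."""

    feature_id: str
    vip_overall: float
    vip_pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def vip_records(
    model: PLSDAModel,
    feature_ids: list[str],
    pairwise: dict[tuple[str, str], np.ndarray] | None = None,
) -> list[VIPRecord]:
    overall = vip(model)
    records = []
    for j, fid in enumerate(feature_ids):
        pw = {pair: float(v[j]) for pair, v in (pairwise or {}).items()}
        records.append(VIPRecord(fid, float(overall[j]), pw))
    return records


def _osc_filter(x: np.ndarray, y: np.ndarray, n_orth: int = 1
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove y-orthogonal variation (orthogonal-signal correction).

    Returns the filtered matrix plus the orthogonal scores and loadings.
    """
    e = x.copy()
    t_orth = np.zeros((x.shape[0], n_orth))
    p_orth = np.zeros((x.shape[1], n_orth))
    for a in range(n_orth):
        w = e.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = e @ w
        p = e.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            break  # no orthogonal variation left
        wo /= norm
        to = e @ wo
        po = e.T @ to / (to @ to)
        e = e - np.outer(to, po)
        t_orth[:, a], p_orth[:, a] = to, po
    return e, t_orth, p_orth


def pairwise_oplsda_vip(
    x: np.ndarray,
    labels,
    class_pairs: list[tuple[str, str]] | None = None,
    n_orth: int = 1,
) -> dict[tuple[str, str], np.ndarray]:
    """Pairwise-contrast VIP profiles from one-vs-one OPLS-DA.

    For each class pair the rows of those two classes are extracted and
    centered, one orthogonal component is removed, and a single predictive
    PLS component is fitted; its VIP is sqrt(p) |w_j| / ||w||.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if class_pairs is None:
        class_pairs = list(itertools.combinations(sorted(set(labels)), 2))
    out: dict[tuple[str, str], np.ndarray] = {}
    for a_cls, b_cls in class_pairs:
        mask = (labels == a_cls) | (labels == b_cls)
        if not (labels == a_cls).any() or not (labels == b_cls).any():
            raise ValueError(f"empty class in pair ({a_cls}, {b_cls})")
        xs = x[mask]
        y = np.where(labels[mask] == a_cls, 1.0, 0.0)
        xs = xs - xs.mean(axis=0)
        y = y - y.mean()
        e, _, _ = _osc_filter(xs, y, n_orth=n_orth)
        w = e.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        out[(a_cls, b_cls)] = np.sqrt(len(w)) * np.abs(w)
    return out


def oplsda_components(x: np.ndarray, labels, pair: tuple[str, str],
                      n_orth: int = 1):
    """Predictive and orthogonal scores for one pair (for diagnostics)."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    a_cls, b_cls = pair
    mask = (labels == a_cls) | (labels == b_cls)
    xs = x[mask] - x[mask].mean(axis=0)
    y = np.where(labels[mask] == a_cls, 1.0, 0.0)
    y = y - y.mean()
    e, t_orth, _ = _osc_filter(xs, y, n_orth=n_orth)
    w = e.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    return e @ w, t_orth


def select_markers(records: list[VIPRecord], cutoff: float = 0.83
                   ) -> list[VIPRecord]:
    """Features with overall VIP strictly above the cutoff, sorted by VIP
    descending (ties by feature_id for determinism)."""
    hits = [r for r in records if r.vip_overall > cutoff]
    hits.sort(key=lambda r: (-r.vip_overall, r.feature_id))
    return hits
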