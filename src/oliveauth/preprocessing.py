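"""Scaling / normalization methods and the composite score that ranks them.

Nine pretreatments are supported: pareto, mean_center, autoscale, range,
vast, level, glog_vsn, log2_center, and pqn_pareto (probabilistic quotient
normalization with a QC-median reference followed by Pareto scaling).
Parameters (per-feature means, standard deviations, ranges, the PQN
reference spectrum, the glog lambda) are always estimated on training
samples only and applied unchanged to test or suspect rows, so no
information leaks across the split.

The variance-stabilizing method is implemented as a generalized-log
transform glog(x; lambda) = log((x + sqrt(x^2 + lambda^2)) / 2) with
lambda set to the median non-zero training intensity, followed by mean
centering; it stabilizes multiplicative noise the way arsinh-type models
do without fitting a full error model.

Methods are compared with a weighted composite of model-quality metrics::

    score = 0.15 R2X + 0.15 R2Y + 0.20 Q2 + 0.15 (1 - RMSEE)
          + 0.30 (1 - RMSEP) + 0.01 acc_train + 0.02 acc_test + 0.02 acc_cv
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from oliveauth.feature_table import FeatureTable

__all__ = [
    "SCALING_METHODS",
    "ScalingParams",
    "ScalingScore",
    "fit_scaling",
    "apply_scaling",
    "apply_scaling_matrix",
    "inverse_scaling_matrix",
    "pqn_normalize",
    "pqn_factors",
    "score_scaling_method",
    "rank_scalings",
]

SCALING_METHODS = (
    "pareto",
    "mean_center",
    "autoscale",
    "range",
    "vast",
    "level",
    "glog_vsn",
    "log2_center",
    "pqn_pareto",
)

#: composite-score weights (metric, weight, higher_is_better)
SCORE_WEIGHTS = {
    "r2x": 0.15,
    "r2y": 0.15,
    "q2": 0.20,
    "rmsee": 0.15,   # enters as (1 - rmsee)
    "rmsep": 0.30,   # enters as (1 - rmsep)
    "acc_train": 0.01,
    "acc_test": 0.02,
    "acc_cv": 0.02,
}


@dataclass
class ScalingParams:
    """Training-derived parameters for one scaling method."""

    method: str
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None          # sample sd, n-1 denominator
    min: np.ndarray | None = None
    max: np.ndarray | None = None
    log2_mean: np.ndarray | None = None   # mean of log2(x + 1)
    glog_lambda: float | None = None
    glog_mean: np.ndarray | None = None
    pqn_reference: np.ndarray | None = None
    n_features: int = 0


@dataclass
class ScalingScore:
    """Model-quality metrics and their weighted composite for one method."""

    r2x: float
    r2y: float
    q2: float
    rmsee: float
    rmsep: float
    acc_train: float
    acc_test: float
    acc_cv: float
    score: float = field(init=False)

    def __post_init__(self) -> None:
        self.score = score_value(self)


def score_value(s: "ScalingScore") -> float:
    return (
        0.15 * s.r2x
        + 0.15 * s.r2y
        + 0.20 * s.q2
        + 0.15 * (1.0 - s.rmsee)
        + 0.30 * (1.0 - s.rmsep)
        + 0.01 * s.acc_train
        + 0.02 * s.acc_test
        + 0.02 * s.acc_cv
    )


def score_scaling_method(**metrics: float) -> ScalingScore:
    """Build a ScalingScore from its components (all eight are required)."""
    required = set(SCORE_WEIGHTS)
    missing = required - set(metrics)
    if missing:
        raise ValueError(f"missing score components: {sorted(missing)}")
    return ScalingScore(**{k: float(metrics[k]) for k in required})


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise division with the 0/0 -> 0 convention for degenerate
    (constant or zero-mean) columns."""
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    np.divide(num, den, out=out, where=den != 0)
    return out


def pqn_factors(matrix: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-row most-probable dilution factors: median of x_ij / ref_j over
    features where both the reference and the row are positive."""
    reference = np.asarray(reference, dtype=float)
    if not np.any(reference > 0):
        raise ValueError("reference spectrum is all zero")
    factors = np.empty(matrix.shape[0])
    for i, row in enumerate(matrix):
        mask = (reference > 0) & (row > 0)
        if not mask.any():
            raise ValueError(f"row {i} has no positive overlap with reference")
        factors[i] = np.median(row[mask] / reference[mask])
    return factors


def pqn_normalize(
    matrix: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row by its most-probable dilution factor.

    Returns the normalized matrix and the per-row factors.  Scale-invariant:
    multiplying a row by c > 0 leaves its normalized row unchanged.
    """
    factors = pqn_factors(matrix, reference)
    return matrix / factors[:, None], factors


def fit_scaling(table: FeatureTable, method: str) -> ScalingParams:
    """Estimate scaling parameters from the table's training sample rows.

    The PQN reference spectrum is the per-feature median of the QC rows
    when QCs are present, else the median of the sample rows.
    """
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}")
    x = table.sample_matrix
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    params = ScalingParams(method=method, n_features=x.shape[1])
    if method == "pqn_pareto":
        qc = table.intensities[table.role_mask("qc")]
        ref = np.median(qc, axis=0) if len(qc) else np.median(x, axis=0)
        params.pqn_reference = ref
        x, _ = pqn_normalize(x, ref)
    if method in ("pareto", "mean_center", "autoscale", "range", "vast",
                  "level", "pqn_pareto"):
        params.mean = x.mean(axis=0)
        params.sd = x.std(axis=0, ddof=1)
        params.min = x.min(axis=0)
        params.max = x.max(axis=0)
    elif method == "log2_center":
        params.log2_mean = np.log2(x + 1.0).mean(axis=0)
    elif method == "glog_vsn":
        nz = x[x > 0]
        params.glog_lambda = float(np.median(nz)) if nz.size else 1.0
        params.glog_mean = _glog(x, params.glog_lambda).mean(axis=0)
    return params


def _glog(x: np.ndarray, lam: float) -> np.ndarray:
    return np.log((x + np.sqrt(x * x + lam * lam)) / 2.0)


def apply_scaling_matrix(x: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Apply a fitted scaling to an intensity matrix (rows = any samples)."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != params.n_features:
        raise ValueError("feature count does not match fitted parameters")
    m = params.method
    if m == "pqn_pareto":
        x, _ = pqn_normalize(x, params.pqn_reference)
        return _safe_div(x - params.mean, np.sqrt(params.sd))
    if m == "pareto":
        return _safe_div(x - params.mean, np.sqrt(params.sd))
    if m == "mean_center":
        return x - params.mean
    if m == "autoscale":
        return _safe_div(x - params.mean, params.sd)
    if m == "range":
        return _safe_div(x - params.mean, params.max - params.min)
    if m == "vast":
        z = _safe_div(x - params.mean, params.sd)
        return z * _safe_div(params.mean, params.sd)
    if m == "level":
        return _safe_div(x - params.mean, params.mean)
    if m == "log2_center":
        return np.log2(x + 1.0) - params.log2_mean
    if m == "glog_vsn":
        return _glog(x, params.glog_lambda) - params.glog_mean
    raise ValueError(f"unknown scaling method {m!r}")


def inverse_scaling_matrix(z: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Invert a fitted scaling where the transform is invertible.

    Defined for pareto, mean_center, autoscale, range, level, log2_center
    and glog_vsn on non-degenerate columns; vast and pqn_pareto are not
    row-wise invertible from the scaled values alone.
    """
    m = params.method
    if m == "pareto":
        return z * np.sqrt(params.sd) + params.mean
    if m == "mean_center":
        return z + params.mean
    if m == "autoscale":
        return z * params.sd + params.mean
    if m == "range":
        return z * (params.max - params.min) + params.mean
    if m == "level":
        return z * params.mean + params.mean
    if m == "log2_center":
        return np.exp2(z + params.log2_mean) - 1.0
    if m == "glog_vsn":
        y = np.exp(z + params.glog_mean)
        lam = params.glog_lambda
        return y - lam * lam / (4.0 * y)
    raise ValueError(f"inverse not defined for method {m!r}")


def apply_scaling(table: FeatureTable, params: ScalingParams) -> FeatureTable:
    """Apply a fitted scaling to every row of a feature table.

    Scaled intensities are legitimately negative, so the non-negativity
    check of the raw-table constructor is bypassed.
    """
    scaled = apply_scaling_matrix(table.intensities, params)
    out = FeatureTable.__new__(FeatureTable)
    out.samples = table.samples.copy().reset_index(drop=True)
    out.features = table.features.copy().reset_index(drop=True)
    out.intensities = scaled
    return out


def rank_scalings(
    table: FeatureTable,
    split,
    methods: tuple[str, ...] = SCALING_METHODS,
    n_lv: int = 3,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[tuple[str, ScalingScore]]:
    """Fit the classifier under each scaling method and rank by composite score.

    For each method: parameters are fitted on the training rows, applied to
    training and test rows, a PLS-DA with ``n_lv`` latent variables is
    fitted, and R2X/R2Y/Q2, RMSEE/RMSEP and the three accuracies feed the
    weighted score.  Returned sorted by score, descending (ties keep the
    method order given).
    """
    from oliveauth import chemometrics as chem
    from oliveauth import validation as val

    train_tab = table.subset_samples(split.train_ids)
    test_tab = table.subset_samples(split.test_ids)
    y_train = train_tab.sample_classes
    y_test = test_tab.sample_classes
    results = []
    for method in methods:
        params = fit_scaling(train_tab, method)
        x_train = apply_scaling_matrix(train_tab.sample_matrix, params)
        x_test = apply_scaling_matrix(test_tab.sample_matrix, params)
        model = chem.fit_plsda(x_train, y_train, n_lv)
        metrics = val.compute_metrics(
            model, x_train, y_train, x_test, y_test,
            cv_folds=cv_folds, seed=seed,
        )
        score = score_scaling_method(
            r2x=metrics.r2x,
            r2y=metrics.r2y,
            q2=metrics.q2,
            rmsee=metrics.rmsee,
            rmsep=metrics.rmsep,
            acc_train=1.0 - metrics.error_train,
            acc_test=1.0 - metrics.error_test,
            acc_cv=1.0 - metrics.error_cv,
        )
        results.append((method, score))
    results.sort(key=lambda ms: -ms[1].score)
    return results
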