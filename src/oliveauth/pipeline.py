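"""End-to-end authenticity workflow orchestration.

Stages, in order: simulate (or load) -> curate (blank filter, duplicate
merge) -> split (Kennard-Stone) -> scale (fixed method or composite-score
auto-selection) -> train (PLS-DA, latent variables fixed or CV-selected)
-> validate (fit statistics, ROC, permutation test, outlier diagnostics)
-> markers (VIP cutoff + pairwise OPLS-DA profiles) -> annotate (optional
candidate list) -> suspects (classify the held-back harvest-year set).

Scaling parameters for the classifier are estimated on training rows only
and applied to test and suspect rows; the Kennard-Stone distance matrix
uses an all-sample Pareto scaling, which touches no class labels.  All
randomness is routed through the single configured seed, so re-running a
config reproduces every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from oliveauth import chemometrics as chem
from oliveauth import validation as val
from oliveauth.feature_table import (
    FeatureTable,
    filter_blank_features,
    merge_duplicates,
    read_table,
    write_table,
)
from oliveauth.preprocessing import (
    SCALING_METHODS,
    apply_scaling_matrix,
    fit_scaling,
    rank_scalings,
)
from oliveauth.splitting import Split, kennard_stone
from oliveauth.synthetic import SyntheticSpec, generate, write_truth

logger = logging.getLogger("oliveauth")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    out_dir: str = "run"
    table_path: str | None = None      # None -> simulate
    suspect_path: str | None = None
    blank_fold: float = 3.0
    mz_tol: float = 0.005
    rt_tol: float = 0.1
    scaling: str = "pareto"            # method name or "auto"
    n_train: int | None = 51
    train_frac: float | None = None
    n_lv: int | str = 3                # count or "auto"
    cv_folds: int = 5
    max_lv: int = 10
    vip_cutoff: float = 0.83
    n_permutations: int = 20
    seed: int = 42
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.scaling != "auto" and self.scaling not in SCALING_METHODS:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if not 0 < self.vip_cutoff:
            raise ValueError("vip_cutoff must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be non-negative")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    table: FeatureTable
    split: Split
    scaling_method: str
    scaling_ranking: list | None
    model: chem.PLSDAModel
    metrics: val.ModelMetrics
    roc: list[val.ROCCurve]
    permutation: val.PermutationResult | None
    diagnostics: val.OutlierDiagnostics
    markers: list[chem.VIPRecord]
    suspects: val.SuspectResult | None
    truth: pd.DataFrame | None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %-9s %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; writes artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- simulate or load -------------------------------------------------
    truth = None
    suspect_table = None
    if config.table_path is None:
        spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
        bundle = _stage("simulate")(generate)(spec)
        table, suspect_table, truth = bundle.table, bundle.suspect_table, bundle.truth
        write_table(table, out / "table.csv")
        write_table(suspect_table, out / "suspects.csv")
        write_truth(bundle, out / "truth.csv")
    else:
        table = _stage("load")(read_table)(config.table_path)
        if config.suspect_path:
            suspect_table = read_table(config.suspect_path)

    # --- curate -----------------------------------------------------------
    @_stage("curate")
    def curate(t: FeatureTable) -> FeatureTable:
        if t.role_mask("blank").any():
            t = filter_blank_features(t, fold=config.blank_fold)
        return merge_duplicates(t, mz_tol=config.mz_tol, rt_tol=config.rt_tol)

    curated = curate(table)
    if suspect_table is not None:
        suspect_table = suspect_table.subset_features(
            list(curated.features["feature_id"])
        )
    write_table(curated, out / "curated.csv")

    # --- split ------------------------------------------------------------
    n_samples = len(curated.sample_ids)
    n_train = config.n_train
    if n_train is None:
        frac = config.train_frac if config.train_frac is not None else 0.785
        n_train = int(round(frac * n_samples))
    split = _stage("split")(kennard_stone)(curated, n_train)
    pd.DataFrame(
        {
            "sample_id": split.train_ids + split.test_ids,
            "subset": ["train"] * len(split.train_ids)
            + ["test"] * len(split.test_ids),
        }
    ).to_csv(out / "split.csv", index=False)

    # --- scaling selection -------------------------------------------------
    ranking = None
    method = config.scaling
    n_lv_for_ranking = config.n_lv if isinstance(config.n_lv, int) else 3
    if method == "auto":
        ranking = _stage("scale")(rank_scalings)(
            curated, split, n_lv=n_lv_for_ranking,
            cv_folds=config.cv_folds, seed=config.seed,
        )
        pd.DataFrame(
            [
                {"method": m, **dataclasses.asdict(s)}
                for m, s in ranking
            ]
        ).to_csv(out / "scaling_ranking.csv", index=False)
        method = ranking[0][0]
    train_tab = curated.subset_samples(split.train_ids)
    test_tab = curated.subset_samples(split.test_ids)
    params = fit_scaling(train_tab, method)
    x_train = apply_scaling_matrix(train_tab.sample_matrix, params)
    x_test = apply_scaling_matrix(test_tab.sample_matrix, params)
    y_train = train_tab.sample_classes
    y_test = test_tab.sample_classes

    # --- train ------------------------------------------------------------
    @_stage("train")
    def train():
        if config.n_lv == "auto":
            n_lv, _ = chem.select_n_lv(
                x_train, y_train, k=config.cv_folds,
                max_lv=config.max_lv, seed=config.seed,
            )
        else:
            n_lv = int(config.n_lv)
        return chem.fit_plsda(
            x_train, y_train, n_lv, training_ids=split.train_ids
        )

    model = train()
    _write_model(model, params, out / "model.json")

    # --- validate ----------------------------------------------------------
    @_stage("validate")
    def validate():
        metrics = val.compute_metrics(
            model, x_train, y_train, x_test, y_test,
            cv_folds=config.cv_folds, seed=config.seed,
        )
        x_all = apply_scaling_matrix(curated.sample_matrix, params)
        _, _, proba = chem.predict(model, x_all)
        roc = val.roc_curves(proba, curated.sample_classes, model.classes)
        perm = None
        if config.n_permutations:
            perm = val.permutation_test(
                x_train, y_train, n_perm=config.n_permutations,
                seed=config.seed, n_lv=model.n_lv, cv_folds=config.cv_folds,
            )
        diag = val.outlier_diagnostics(
            model, x_train, sample_ids=split.train_ids
        )
        return metrics, roc, perm, diag

    metrics, roc, perm, diag = validate()
    _write_report(metrics, roc, perm, diag, out / "validation.json")

    # --- markers ----------------------------------------------------------
    @_stage("markers")
    def markers():
        pairwise = chem.pairwise_oplsda_vip(x_train, y_train)
        records = chem.vip_records(
            model, list(curated.features["feature_id"]), pairwise
        )
        return chem.select_markers(records, cutoff=config.vip_cutoff)

    selected = markers()
    _write_markers(selected, curated, out / "markers.csv")

    # --- suspects ----------------------------------------------------------
    suspects = None
    if suspect_table is not None and len(suspect_table.samples):
        suspects = _stage("suspects")(val.classify_suspects)(
            model, params, suspect_table, x_train=x_train
        )
        pd.DataFrame(
            {
                "sample_id": suspects.sample_ids,
                "assigned": suspects.assigned,
                "hotelling_t2": suspects.diagnostics.hotelling_t2,
                "q_residual": suspects.diagnostics.q_residual,
                "outlier": suspects.diagnostics.outliers(),
            }
        ).to_csv(out / "suspect_assignments.csv", index=False)

    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    del rng  # single seed is threaded explicitly through every stage
    return PipelineResult(
        config=config, table=table, split=split, scaling_method=method,
        scaling_ranking=ranking, model=model, metrics=metrics, roc=roc,
        permutation=perm, diagnostics=diag, markers=selected,
        suspects=suspects, truth=truth,
    )


def _write_model(model, params, path) -> None:
    payload = {
        "n_lv": model.n_lv,
        "classes": model.classes,
        "scaling_method": params.method,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean.tolist(),
        "x_weights": model.w.tolist(),
        "x_loadings": model.p.tolist(),
        "y_loadings": model.c.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def _write_report(metrics, roc, perm, diag, path) -> None:
    payload = {
        "r2x": metrics.r2x,
        "r2y": metrics.r2y,
        "q2": metrics.q2,
        "rmsee": metrics.rmsee,
        "rmsep": metrics.rmsep,
        "error_train": metrics.error_train,
        "error_cv": metrics.error_cv,
        "error_test": metrics.error_test,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "auc": {c.class_label: c.auc for c in roc},
        "t2_limit_95": diag.t2_limit_95,
        "q_limit_95": diag.q_limit_95,
    }
    if perm is not None:
        payload["permutation"] = {
            "observed_q2": perm.observed_q2,
            "observed_r2y": perm.observed_r2y,
            "permuted_q2": perm.permuted_q2.tolist(),
            "p_value": perm.p_value,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def _write_markers(selected, curated, path) -> None:
    feat = curated.features.set_index("feature_id")
    rows = []
    for rec in selected:
        row = {
            "feature_id": rec.feature_id,
            "mz": feat.loc[rec.feature_id, "mz"],
            "rt": feat.loc[rec.feature_id, "rt"],
            "vip_overall": rec.vip_overall,
        }
        for (a, b), v in rec.vip_pairwise.items():
            row[f"vip_{a}_vs_{b}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
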