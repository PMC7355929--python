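"""Seeded generator of synthetic untargeted LC-MS feature tables.

Emulates the three-origin table-olive study design: 65 samples
(20 Greece / 24 Egypt / 21 Chile), pooled QC injections equal to the mean
of all sample rows plus small analytical noise, procedural blanks carrying
only background contaminant features, injected near-duplicate feature
pairs, and an 11-sample "suspect" set drawn from the Greek generative
model with an extra harvest-year multiplicative shift.

Intensity model, feature j in sample i::

    x_ij = baseline_j * class_effect_ij * dilution_i * noise_ij

with a log-normal baseline, class_effect = ``marker_fold_change`` when j is
a marker of sample i's class (else 1), a per-sample log-normal dilution
factor, and multiplicative log-normal measurement noise of coefficient of
variation ``noise_cv``.  Every draw comes from one seeded generator: equal
seeds give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oliveauth.feature_table import CLASS_LABELS, FeatureTable

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate", "write_truth"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study design (defaults = study layout)."""

    n_per_class: tuple[int, int, int] = (20, 24, 21)
    n_features: int = 2000
    n_markers_per_class: int = 10
    marker_fold_change: float = 5.0
    base_log_mean: float = 12.0   # natural-log mean of baseline intensity
    base_log_sd: float = 1.0
    dilution_sd: float = 0.15     # log-sd of per-sample dilution factor
    noise_cv: float = 0.10        # CV of multiplicative measurement noise
    n_qc: int = 6
    n_blank: int = 4
    blank_contaminant_fraction: float = 0.05
    n_duplicates: int = 10
    n_suspect: int = 11
    year_shift_sd: float = 0.15   # log-sd of the shared harvest-year effect
    seed: int = 42

    def __post_init__(self) -> None:
        counts = (
            *self.n_per_class, self.n_features, self.n_markers_per_class,
            self.n_qc, self.n_blank, self.n_duplicates, self.n_suspect,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be at least 1")
        # fold change exactly 1 is the deliberate no-signal control
        n_special = 3 * self.n_markers_per_class + int(
            round(self.blank_contaminant_fraction * self.n_features)
        )
        if n_special > self.n_features:
            raise ValueError("markers + contaminants exceed n_features")


@dataclass
class SyntheticBundle:
    """Generated tables plus the per-feature ground truth."""

    table: FeatureTable          # samples + QCs + blanks
    suspect_table: FeatureTable  # the harvest-year robustness set
    truth: pd.DataFrame          # feature_id, marker_class, duplicate_of,
                                 # is_contaminant
    dilution_factors: pd.Series = field(default=None)  # per sample_id


def _draw_descriptors(
    rng: np.random.Generator, n: int, min_mz_gap: float = 0.012,
    min_rt_gap: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (m/z, rt) uniform in the scan range [80, 1000] Da x [0.5, 15] min,
    rejecting accidental near-coincidences so that only the deliberately
    injected duplicate pairs fall within the curation tolerances."""
    mz = rng.uniform(80.0, 1000.0, size=n)
    rt = rng.uniform(0.5, 15.0, size=n)
    for _ in range(100):
        order = np.argsort(mz)
        bad: set[int] = set()
        smz, srt = mz[order], rt[order]
        for a in range(n):
            b = a + 1
            while b < n and smz[b] - smz[a] <= min_mz_gap:
                if abs(srt[b] - srt[a]) <= min_rt_gap:
                    bad.add(int(order[b]))
                b += 1
        if not bad:
            return mz, rt
        idx = np.array(sorted(bad))
        mz[idx] = rng.uniform(80.0, 1000.0, size=len(idx))
        rt[idx] = rng.uniform(0.5, 15.0, size=len(idx))
    raise RuntimeError("could not place features with minimum separation")


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate a full synthetic bundle from a seeded spec."""
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    n_samples = sum(spec.n_per_class)
    classes = np.repeat(CLASS_LABELS, spec.n_per_class)

    mz, rt = _draw_descriptors(rng, p)
    baseline = rng.lognormal(spec.base_log_mean, spec.base_log_sd, size=p)

    # disjoint special feature sets: contaminants first, then class markers
    n_cont = int(round(spec.blank_contaminant_fraction * p))
    special = rng.choice(p, size=n_cont + 3 * spec.n_markers_per_class,
                         replace=False)
    contaminants = np.sort(special[:n_cont])
    marker_sets = {
        cls: np.sort(special[n_cont + k * spec.n_markers_per_class:
                             n_cont + (k + 1) * spec.n_markers_per_class])
        for k, cls in enumerate(CLASS_LABELS)
    }

    noise_sigma = float(np.sqrt(np.log1p(spec.noise_cv ** 2)))

    def sample_rows(n: int, cls_of_row: np.ndarray,
                    extra: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
        effect = np.ones((n, p))
        for cls, idx in marker_sets.items():
            rows = cls_of_row == cls
            if rows.any() and len(idx):
                effect[np.ix_(rows, idx)] = spec.marker_fold_change
        dilution = rng.lognormal(0.0, spec.dilution_sd, size=n)
        noise = rng.lognormal(0.0, noise_sigma, size=(n, p))
        x = baseline[None, :] * effect * dilution[:, None] * noise
        if extra is not None:
            x = x * extra[None, :]
        return x, dilution

    x_samples, dil_samples = sample_rows(n_samples, classes)

    # QC rows: pooled mean of all sample rows, re-measured with noise
    qc = x_samples.mean(axis=0)[None, :] * rng.lognormal(
        0.0, noise_sigma, size=(spec.n_qc, p)
    )

    # blanks: only contaminant features, at a level that fails the 3x rule
    blank = np.zeros((spec.n_blank, p))
    if n_cont and spec.n_blank:
        blank[:, contaminants] = (
            baseline[contaminants][None, :]
            * 0.8
            * rng.lognormal(0.0, noise_sigma, size=(spec.n_blank, n_cont))
        )

    # suspect set: Greek generative model with a shared year effect
    year_effect = rng.lognormal(0.0, spec.year_shift_sd, size=p)
    x_suspect, dil_suspect = sample_rows(
        spec.n_suspect, np.repeat("Greece", spec.n_suspect), extra=year_effect
    )

    feature_ids = [f"F{j:05d}" for j in range(p)]

    # injected near-duplicate columns (slightly lower intensity copies)
    eligible = np.setdiff1d(
        np.arange(p), np.concatenate([contaminants, *marker_sets.values()])
    )
    dup_sources = rng.choice(eligible, size=spec.n_duplicates, replace=False)
    dup_ids, dup_mz, dup_rt = [], [], []
    dup_cols_samples, dup_cols_qc, dup_cols_blank, dup_cols_suspect = [], [], [], []
    for src in dup_sources:
        dup_ids.append(f"F{src:05d}dup")
        dup_mz.append(mz[src] + rng.uniform(-0.003, 0.003))
        dup_rt.append(max(rt[src] + rng.uniform(-0.05, 0.05), 0.0))
        factor = 0.8
        dup_cols_samples.append(x_samples[:, src] * factor)
        dup_cols_qc.append(qc[:, src] * factor)
        dup_cols_blank.append(blank[:, src] * factor)
        dup_cols_suspect.append(x_suspect[:, src] * factor)

    features = pd.DataFrame(
        {
            "feature_id": feature_ids + dup_ids,
            "mz": np.concatenate([mz, dup_mz]) if dup_ids else mz,
            "rt": np.concatenate([rt, dup_rt]) if dup_ids else rt,
        }
    )

    def stack(base: np.ndarray, dup_cols: list[np.ndarray]) -> np.ndarray:
        if not dup_cols:
            return base
        return np.hstack([base, np.column_stack(dup_cols)])

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    qc_ids = [f"QC{i:02d}" for i in range(spec.n_qc)]
    blank_ids = [f"B{i:02d}" for i in range(spec.n_blank)]
    suspect_ids = [f"X{i:03d}" for i in range(spec.n_suspect)]

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids + qc_ids + blank_ids,
            "role": ["sample"] * n_samples
            + ["qc"] * spec.n_qc
            + ["blank"] * spec.n_blank,
            "class_label": list(classes) + [None] * (spec.n_qc + spec.n_blank),
        }
    )
    intensities = np.vstack(
        [
            stack(x_samples, dup_cols_samples),
            stack(qc, dup_cols_qc),
            stack(blank, dup_cols_blank),
        ]
    )
    table = FeatureTable(samples, features, intensities)

    suspect_samples = pd.DataFrame(
        {
            "sample_id": suspect_ids,
            "role": ["suspect"] * spec.n_suspect,
            "class_label": ["Greece"] * spec.n_suspect,
        }
    )
    suspect_table = FeatureTable(
        suspect_samples, features.copy(), stack(x_suspect, dup_cols_suspect)
    )

    marker_class = np.array([None] * p, dtype=object)
    for cls, idx in marker_sets.items():
        marker_class[idx] = cls
    is_cont = np.zeros(p, dtype=bool)
    is_cont[contaminants] = True
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids + dup_ids,
            "marker_class": list(marker_class) + [None] * len(dup_ids),
            "duplicate_of": [None] * p + [f"F{s:05d}" for s in dup_sources],
            "is_contaminant": list(is_cont) + [False] * len(dup_ids),
        }
    )
    dilution = pd.Series(
        np.concatenate([dil_samples, dil_suspect]),
        index=sample_ids + suspect_ids,
        name="dilution_factor",
    )
    return SyntheticBundle(table, suspect_table, truth, dilution)


def write_truth(bundle: SyntheticBundle, path) -> None:
    """Write the per-feature ground-truth table as CSV."""
    bundle.truth.to_csv(path, index=False)
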