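"""Aligned feature-table data model, CSV I/O, and curation.

A feature table is a samples x features intensity matrix with per-feature
m/z (Da) and retention time (min) descriptors and per-sample role
(sample / qc / blank / suspect) and class-label metadata.  Curation
consists of blank-based feature removal (a feature is kept only when its
mean sample intensity is at least ``fold`` times its mean blank intensity)
and single-linkage merging of duplicate features that agree within m/z and
retention-time tolerances, keeping the most intense member of each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "CLASS_LABELS",
    "FeatureTable",
    "read_table",
    "write_table",
    "filter_blank_features",
    "merge_duplicates",
]

ROLES = ("sample", "qc", "blank", "suspect")
CLASS_LABELS = ("Greece", "Egypt", "Chile")


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with descriptors and roles.

    Attributes
    ----------
    samples : DataFrame with columns ``sample_id``, ``role``, ``class_label``
        (class_label is None except for role ``sample`` / ``suspect``).
    features : DataFrame with columns ``feature_id``, ``mz``, ``rt``.
    intensities : float array of shape (n_samples, n_features), >= 0.
    """

    samples: pd.DataFrame
    features: pd.DataFrame
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities are not allowed")
        fids = self.features["feature_id"]
        if fids.duplicated().any():
            raise ValueError("duplicate feature_id")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        bad = ~self.samples["role"].isin(ROLES)
        if bad.any():
            raise ValueError(f"unknown roles: {set(self.samples.loc[bad, 'role'])}")
        if (self.features["mz"] <= 0).any():
            raise ValueError("m/z must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("retention time must be non-negative")

    # -- views ------------------------------------------------------------
    def role_mask(self, role: str) -> np.ndarray:
        return (self.samples["role"] == role).to_numpy()

    @property
    def sample_matrix(self) -> np.ndarray:
        """Intensity rows of role ``sample`` only."""
        return self.intensities[self.role_mask("sample")]

    @property
    def sample_classes(self) -> np.ndarray:
        return self.samples.loc[self.role_mask("sample"), "class_label"].to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.loc[self.role_mask("sample"), "sample_id"])

    def subset_samples(self, sample_ids: list[str]) -> "FeatureTable":
        """Row subset (in the given order); feature set unchanged."""
        index = {sid: i for i, sid in enumerate(self.samples["sample_id"])}
        rows = [index[s] for s in sample_ids]
        return FeatureTable(
            self.samples.iloc[rows].copy(),
            self.features.copy(),
            self.intensities[rows].copy(),
        )

    def subset_features(self, feature_ids: list[str]) -> "FeatureTable":
        """Column subset (in the given order); sample set unchanged."""
        index = {fid: j for j, fid in enumerate(self.features["feature_id"])}
        cols = [index[f] for f in feature_ids]
        return FeatureTable(
            self.samples.copy(),
            self.features.iloc[cols].copy(),
            self.intensities[:, cols].copy(),
        )

    def with_intensities(self, matrix: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.samples.copy(), self.features.copy(), matrix)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.samples.fillna("").equals(other.samples.fillna(""))
            and self.features.equals(other.features)
            and np.array_equal(self.intensities, other.intensities)
        )


def write_table(table: FeatureTable, path) -> None:
    """Write the CSV layout: feature_id header, mz and rt descriptor rows,
    then one row per sample (sample_id, role, class_label, intensities)."""
    fids = list(table.features["feature_id"])
    header = ["sample_id", "role", "class_label"] + fids
    rows = [
        ["mz", "", ""] + [repr(float(v)) for v in table.features["mz"]],
        ["rt", "", ""] + [repr(float(v)) for v in table.features["rt"]],
    ]
    for i, rec in table.samples.iterrows():
        label = rec["class_label"] if pd.notna(rec["class_label"]) else ""
        rows.append(
            [rec["sample_id"], rec["role"], label]
            + [repr(float(v)) for v in table.intensities[i]]
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(x) for x in row) + "\n")


def read_table(path) -> FeatureTable:
    """Inverse of :func:`write_table`; validates all table invariants."""
    df = pd.read_csv(
        path, dtype={"sample_id": str}, keep_default_na=False,
        float_precision="round_trip",
    )
    if list(df.columns[:3]) != ["sample_id", "role", "class_label"]:
        raise ValueError("expected sample_id, role, class_label leading columns")
    fids = list(df.columns[3:])
    if df.iloc[0, 0] != "mz" or df.iloc[1, 0] != "rt":
        raise ValueError("expected mz and rt descriptor rows")
    features = pd.DataFrame(
        {
            "feature_id": fids,
            "mz": df.iloc[0, 3:].astype(float).to_numpy(),
            "rt": df.iloc[1, 3:].astype(float).to_numpy(),
        }
    )
    body = df.iloc[2:]
    samples = pd.DataFrame(
        {
            "sample_id": body["sample_id"].to_numpy(),
            "role": body["role"].to_numpy(),
            "class_label": [c if c else None for c in body["class_label"]],
        }
    )
    intensities = body[fids].astype(float).to_numpy()
    return FeatureTable(samples, features, intensities)


def filter_blank_features(
    table: FeatureTable, fold: float = 3.0, drop_blanks: bool = True
) -> FeatureTable:
    """Remove features dominated by the procedural blank.

    A feature is retained iff mean(sample intensities) >= ``fold`` x
    mean(blank intensities); a feature absent from the blanks (mean 0) is
    always retained.  Blank rows themselves are dropped from the result
    unless ``drop_blanks`` is False.
    """
    blank_mask = table.role_mask("blank")
    if not blank_mask.any():
        raise ValueError("table contains no blank rows")
    sample_mean = table.sample_matrix.mean(axis=0)
    blank_mean = table.intensities[blank_mask].mean(axis=0)
    keep = sample_mean >= fold * blank_mean
    out = FeatureTable(
        table.samples.copy(),
        table.features.loc[keep].copy(),
        table.intensities[:, keep].copy(),
    )
    if drop_blanks:
        keep_rows = ~blank_mask
        out = FeatureTable(
            out.samples.loc[keep_rows].copy(),
            out.features,
            out.intensities[keep_rows],
        )
    return out


def merge_duplicates(
    table: FeatureTable, mz_tol: float = 0.005, rt_tol: float = 0.1
) -> FeatureTable:
    """Merge near-duplicate features by single linkage, keeping the most
    intense member of each group.

    Features with |dm/z| <= ``mz_tol`` Da and |dRT| <= ``rt_tol`` min are
    linked; each connected component is replaced by its member with the
    highest mean intensity (ties broken toward lower m/z).  Retained
    intensity values are never altered; only columns are dropped.
    """
    if mz_tol < 0 or rt_tol < 0:
        raise ValueError("negative tolerance")
    n = len(table.features)
    mz = table.features["mz"].to_numpy()
    rt = table.features["rt"].to_numpy()
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    order = np.argsort(mz, kind="stable")  # ascending m/z, deterministic
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if mz[j] - mz[i] > mz_tol:
                break
            if abs(rt[i] - rt[j]) <= rt_tol:
                union(int(i), int(j))

    mean_int = table.intensities.mean(axis=0)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep = []
    for members in groups.values():
        best = min(members, key=lambda i: (-mean_int[i], mz[i]))
        keep.append(best)
    keep_mask = np.zeros(n, dtype=bool)
    keep_mask[keep] = True  # original column order preserved
    return FeatureTable(
        table.samples.copy(),
        table.features.loc[keep_mask].copy(),
        table.intensities[:, keep_mask].copy(),
    )
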