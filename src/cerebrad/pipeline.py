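"""Cohort-level feature assembly: subjects x (modality, region, feature).

Rows follow manifest order; columns are a fixed lexicographic-by-construction
MultiIndex (modality outer, region 1..n inner, feature in catalogue order),
so a single-modality extraction over 26 regions is a 26 x 57 = 1,482-length
row and the three-modality concatenation is 4,446.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cerebrad.features import FEATURE_NAMES, extract_region_features, DEFAULT_MIN_VOXELS
from cerebrad.synthetic import SubjectImageSet

__all__ = [
    "FeatureMatrix",
    "MedianImputer",
    "assemble_subject",
    "build_feature_matrix",
    "build_feature_matrix_from_manifest",
    "column_index",
]


def column_index(modalities: Sequence[str], n_regions: int) -> pd.MultiIndex:
    """The canonical column MultiIndex (modality, region, feature)."""
    tuples = [
        (m, r, f)
        for m in modalities
        for r in range(1, n_regions + 1)
        for f in FEATURE_NAMES
    ]
    return pd.MultiIndex.from_tuples(tuples, names=["modality", "region", "feature"])


@dataclass
class FeatureMatrix:
    """Subjects x features table with group labels and a degeneracy mask.

    ``values`` holds finite numbers everywhere (degenerate cells carry their
    documented substitutes); ``flags`` marks cells that should be re-imputed
    from the training partition in any fitting procedure.
    """

    values: pd.DataFrame  # index: subject ids; columns: (modality, region, feature)
    labels: pd.Series  # group label per subject
    flags: pd.DataFrame  # bool, same shape as values
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match values index")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.values.columns.get_level_values("modality")))

    def restrict(self, modalities: Sequence[str]) -> "FeatureMatrix":
        """The sub-matrix of the given modalities' columns (order preserved)."""
        missing = [m for m in modalities if m not in self.modalities]
        if missing:
            raise KeyError(f"modalities not present: {missing}")
        cols = self.values.columns.get_level_values("modality").isin(modalities)
        return FeatureMatrix(
            values=self.values.loc[:, cols],
            labels=self.labels,
            flags=self.flags.loc[:, cols],
            provenance={**self.provenance, "restricted_to": list(modalities)},
        )

    def subset(self, subject_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values.loc[list(subject_ids)],
            labels=self.labels.loc[list(subject_ids)],
            flags=self.flags.loc[list(subject_ids)],
            provenance=self.provenance,
        )

    def task_subset(self, positive: Sequence[str] | str, negative: Sequence[str] | str):
        """Rows belonging to a binary task; returns (matrix, y) with y in {0, 1}."""
        pos = [positive] if isinstance(positive, str) else list(positive)
        neg = [negative] if isinstance(negative, str) else list(negative)
        keep = self.labels.isin(pos + neg)
        sub = self.subset(self.labels.index[keep])
        y = sub.labels.isin(pos).astype(int)
        return sub, y

    def to_csv(self, path: str | Path) -> None:
        """Wide CSV (one row per subject) plus a JSON sidecar of metadata."""
        path = Path(path)
        flat = self.values.copy()
        flat.columns = [f"{m}|r{r:02d}|{f}" for m, r, f in self.values.columns]
        flat.insert(0, "group", self.labels)
        flat.to_csv(path, index_label="subject_id")
        sidecar = {
            "columns": [list(map(str, c)) for c in self.values.columns],
            "provenance": self.provenance,
            "n_flagged_cells": int(self.flags.to_numpy().sum()),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


class MedianImputer:
    """Per-column median of non-flagged training cells; reused at test time."""

    def __init__(self) -> None:
        self.medians_: pd.Series | None = None

    def fit(self, values: pd.DataFrame, flags: pd.DataFrame) -> "MedianImputer":
        masked = values.where(~flags)
        med = masked.median(axis=0)
        # columns flagged in every training row: fall back to the substitute values
        med = med.fillna(values.median(axis=0))
        self.medians_ = med
        return self

    def transform(self, values: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("imputer not fitted")
        out = values.copy()
        filler = pd.DataFrame(
            np.broadcast_to(self.medians_.to_numpy(), out.shape),
            index=out.index,
            columns=out.columns,
        )
        return out.where(~flags, filler)


def assemble_subject(
    subject: SubjectImageSet,
    modalities: Sequence[str] | None = None,
    n_levels: int = 32,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> tuple[pd.Series, pd.Series]:
    """One subject's feature row: modalities (outer) x regions (inner) x 57.

    Returns ``(values, flags)`` indexed by the canonical column MultiIndex.
    """
    if modalities is None:
        modalities = tuple(subject.volumes)
    for m in modalities:
        if m not in subject.volumes:
            raise KeyError(f"subject {subject.subject_id!r} is missing modality {m!r}")
    region_ids = [int(r) for r in np.unique(subject.label_map) if r > 0]
    n_regions = max(region_ids)
    vals: list[float] = []
    flgs: list[bool] = []
    for modality in modalities:
        vol = subject.volumes[modality]
        for region in range(1, n_regions + 1):
            rfv = extract_region_features(
                vol, subject.label_map, region, modality=modality,
                n_levels=n_levels, min_voxels=min_voxels,
            )
            vals.extend(rfv.as_array())
            flgs.extend(rfv.flag_array())
    cols = column_index(modalities, n_regions)
    return pd.Series(vals, index=cols), pd.Series(flgs, index=cols)


def build_feature_matrix(
    subjects: Iterable[SubjectImageSet],
    modalities: Sequence[str] | None = None,
    n_levels: int = 32,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    provenance: dict | None = None,
) -> FeatureMatrix:
    """Assemble a cohort of in-memory subjects into a FeatureMatrix."""
    rows, frows, ids, groups = [], [], [], []
    for subject in subjects:
        v, f = assemble_subject(subject, modalities, n_levels=n_levels, min_voxels=min_voxels)
        rows.append(v)
        frows.append(f)
        ids.append(subject.subject_id)
        groups.append(subject.group)
    values = pd.DataFrame(rows, index=ids)
    flags = pd.DataFrame(frows, index=ids)
    labels = pd.Series(groups, index=ids, name="group")
    prov = {"n_levels": n_levels, "min_voxels": min_voxels, **(provenance or {})}
    return FeatureMatrix(values=values, labels=labels, flags=flags, provenance=prov)


def build_feature_matrix_from_manifest(
    manifest: pd.DataFrame | str | Path,
    modalities: Sequence[str],
    n_levels: int = 32,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    skip_bad: bool = False,
) -> FeatureMatrix:
    """Read a cohort from a manifest CSV of NIfTI paths and assemble features.

    Unreadable subjects are collected into a failure report; the run aborts
    with that report unless ``skip_bad``.
    """
    import nibabel as nib

    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    failures: list[str] = []
    subjects: list[SubjectImageSet] = []
    for _, row in manifest.iterrows():
        try:
            volumes = {m: np.asarray(nib.load(row[m]).dataobj, dtype=float) for m in modalities}
            label_map = np.asarray(nib.load(row["label_map"]).dataobj).astype(int)
            subjects.append(
                SubjectImageSet(
                    subject_id=row["subject_id"], group=row["group"],
                    volumes=volumes, label_map=label_map,
                )
            )
        except Exception as exc:  # noqa: BLE001 - reported per subject
            failures.append(f"{row['subject_id']}: {exc}")
    if failures and not skip_bad:
        raise IOError("failed to read subjects:\n" + "\n".join(failures))
    fm = build_feature_matrix(
        subjects, modalities, n_levels=n_levels, min_voxels=min_voxels,
        provenance={"manifest_rows": len(manifest), "failures": failures},
    )
    return fm
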