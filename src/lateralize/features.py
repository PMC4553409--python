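"""The subjects x features table and its construction from imaging data.

Every feature carries exactly one of six sub-category tags:
ALFF, fALFF, ReHo (voxelwise maps), FC (Fisher-z region pairs),
NMglobal and NMnodal (graph metrics). Feature names are canonical strings —
``alff@voxel_i_j_k`` (0-based array indices), ``fc@Ra__Rb`` and
``metric@threshold[@roi]`` — so selections and importance reports are
stable and joinable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import (extract_roi_timeseries, fc_matrix, regress_nuisance)
from .graphs import DEFAULT_THRESHOLDS, network_feature_block
from .images import BoldImage, Parcellation
from .voxel import DEFAULT_BAND, voxel_feature_maps

__all__ = ["FeatureTable", "SUBCATEGORIES", "build_subject_features",
           "build_feature_table"]

SUBCATEGORIES = ("ALFF", "fALFF", "ReHo", "FC", "NMglobal", "NMnodal")


@dataclass
class FeatureTable:
    """Subjects x named features, each tagged with one sub-category.

    ``values``: DataFrame (index = subject ids, columns = feature names);
    ``subcategory``: Series mapping feature name -> tag;
    ``labels``: Series mapping subject id -> 'L' or 'R'.
    """

    values: pd.DataFrame
    subcategory: pd.Series
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        missing = set(self.values.columns) - set(self.subcategory.index)
        if missing:
            raise ValueError(f"features without a sub-category tag: {sorted(missing)[:5]}")
        bad = set(self.subcategory.unique()) - set(SUBCATEGORIES)
        if bad:
            raise ValueError(f"unknown sub-categories: {bad}")
        if not set(self.values.index) <= set(self.labels.index):
            raise ValueError("every subject needs a label")
        if not set(self.labels.loc[self.values.index]) <= {"L", "R"}:
            raise ValueError("labels must be 'L' or 'R'")
        self.subcategory = self.subcategory.loc[self.values.columns]
        self.labels = self.labels.loc[self.values.index]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def features_of(self, subcat: str) -> list[str]:
        return list(self.subcategory.index[self.subcategory == subcat])

    def subset_subjects(self, ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[ids], self.subcategory.copy(),
                            self.labels.loc[ids])

    def select_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(self.values[names], self.subcategory.loc[names],
                            self.labels.copy())

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels.loc[out.index])
        out.to_csv(path, sep="\t", index_label="subject_id")

    def tags_to_tsv(self, path) -> None:
        self.subcategory.rename("subcategory").to_csv(path, sep="\t",
                                                      index_label="feature")

    @classmethod
    def from_tsv(cls, values_path, tags_path) -> "FeatureTable":
        df = pd.read_csv(values_path, sep="\t", index_col="subject_id")
        labels = df.pop("label")
        tags = pd.read_csv(tags_path, sep="\t", index_col="feature")["subcategory"]
        return cls(values=df, subcategory=tags, labels=labels)


def build_subject_features(bold: BoldImage, confounds, parcellation: Parcellation,
                           band=DEFAULT_BAND, fwhm_mm: float = 4.0,
                           thresholds=DEFAULT_THRESHOLDS, n_null: int = 100,
                           seed: int = 0) -> tuple[pd.Series, pd.Series]:
    """All candidate features for one subject.

    Returns (values, tags): the voxelwise standardized ALFF/fALFF/ReHo values
    at every in-mask voxel, the upper-triangle Fisher-z FCs after nuisance
    regression, and the graph-metric block over the given thresholds.
    """
    maps = voxel_feature_maps(bold, band=band, fwhm_mm=fwhm_mm)
    coords = np.argwhere(bold.mask)
    names, values, tags = [], [], []
    for tag, vol in (("ALFF", maps.alff), ("fALFF", maps.falff), ("ReHo", maps.reho)):
        prefix = tag.lower()
        for x, y, z in coords:
            names.append(f"{prefix}@voxel_{x}_{y}_{z}")
            values.append(vol[x, y, z])
            tags.append(tag)

    ts = regress_nuisance(extract_roi_timeseries(bold, parcellation), confounds)
    cm = fc_matrix(ts)
    roi_names = parcellation.names
    R = len(cm.roi_ids)
    for i in range(R):
        for j in range(i + 1, R):
            a = roi_names.get(cm.roi_ids[i], f"R{cm.roi_ids[i]}")
            b = roi_names.get(cm.roi_ids[j], f"R{cm.roi_ids[j]}")
            names.append(f"fc@{a}__{b}")
            values.append(cm.z[i, j])
            tags.append("FC")

    block = network_feature_block(cm, thresholds=thresholds, roi_names=roi_names,
                                  n_null=n_null, seed=seed)
    names.extend(block.index)
    values.extend(block["value"])
    tags.extend(block["subcategory"])
    return (pd.Series(values, index=names),
            pd.Series(tags, index=names))


def build_feature_table(subjects, parcellation: Parcellation,
                        band=DEFAULT_BAND, fwhm_mm: float = 4.0,
                        thresholds=DEFAULT_THRESHOLDS, n_null: int = 100,
                        seed: int = 0,
                        subject_ids=None) -> FeatureTable:
    """Feature table for a cohort of (bold, confounds, label) triples."""
    rows, labels, tags = [], {}, None
    ids = subject_ids or [f"sub-{i + 1:02d}" for i in range(len(subjects))]
    for sid, (bold, conf, label) in zip(ids, subjects):
        vals, t = build_subject_features(bold, conf, parcellation, band=band,
                                         fwhm_mm=fwhm_mm, thresholds=thresholds,
                                         n_null=n_null, seed=seed)
        rows.append(vals.rename(sid))
        labels[sid] = label
        tags = t
    values = pd.DataFrame(rows)
    return FeatureTable(values=values, subcategory=tags,
                        labels=pd.Series(labels))
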