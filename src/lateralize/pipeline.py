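"""End-to-end pipeline: simulate -> features -> group stats -> LOOCV -> report.

Every stage writes its artifacts under the output directory and all
randomness flows from the config seed, so two identical invocations produce
byte-identical summaries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .features import build_feature_table, FeatureTable
from .images import BoldImage, Parcellation
from .model import LateralityModel, LateralityResults
from .stats import cluster_filter, mann_whitney_map
from .synthetic import simulate_cohort
from .voxel import voxel_feature_maps

__all__ = ["run_pipeline", "load_cohort_dir"]


def load_cohort_dir(indir) -> tuple[list, Parcellation]:
    """Read a cohort written by :func:`lateralize.synthetic.write_cohort`."""
    indir = Path(indir)
    atlas_path = indir / "atlas.nii.gz"
    if not atlas_path.exists():
        raise FileNotFoundError(f"missing atlas file: {atlas_path}")
    parc = Parcellation.load(atlas_path)
    table = pd.read_csv(indir / "subjects.tsv", sep="\t")
    subjects = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        bold = BoldImage.load(indir / f"{sid}_bold.nii.gz", mask=parc.brain_mask)
        conf = pd.read_csv(indir / f"{sid}_confounds.tsv", sep="\t")
        subjects.append((bold, conf, row["label"]))
    return subjects, parc


def _group_stats_report(subjects, config: PipelineConfig, outdir: Path) -> dict:
    """Voxelwise U-test + cluster-extent reference comparison on the three maps."""
    maps = {"alff": [], "falff": [], "reho": []}
    labels = []
    for bold, _conf, label in subjects:
        vm = voxel_feature_maps(bold, band=config.band, fwhm_mm=config.fwhm_mm)
        maps["alff"].append(vm.alff)
        maps["falff"].append(vm.falff)
        maps["reho"].append(vm.reho)
        labels.append(label)
    labels = np.array(labels)
    mask = subjects[0][0].mask
    rows = []
    for name, stack in maps.items():
        stack = np.stack(stack)
        sig = mann_whitney_map(stack[labels == "L"], stack[labels == "R"],
                               mask, alpha=config.group_alpha)
        report = cluster_filter(sig, connectivity=6,
                                min_size=config.min_cluster_size,
                                alpha=config.group_alpha)
        for i, c in enumerate(report.clusters):
            rows.append({"map": name, "cluster": i + 1, "size": c.size,
                         "peak_x": c.peak[0], "peak_y": c.peak[1],
                         "peak_z": c.peak[2]})
    df = pd.DataFrame(rows, columns=["map", "cluster", "size",
                                     "peak_x", "peak_y", "peak_z"])
    df.to_csv(outdir / "group_clusters.tsv", sep="\t", index=False)
    return {"n_clusters": {name: int((df["map"] == name).sum())
                           for name in maps}}


def run_pipeline(config: PipelineConfig, outdir,
                 cohort_dir=None, group_stats: bool = False
                 ) -> LateralityResults:
    """Run the full analysis and write stage artifacts under ``outdir``.

    The cohort is simulated from ``config.cohort`` unless ``cohort_dir``
    points at a previously written cohort. Writes the feature table, the
    per-fold selections, the importance report and a deterministic
    ``summary.yaml``; returns the fitted results object.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort_dir is not None:
        subjects, parc = load_cohort_dir(cohort_dir)
    else:
        if config.cohort is None:
            raise ValueError("config.cohort is unset and no cohort_dir given")
        subjects, parc = simulate_cohort(config.cohort)

    table = build_feature_table(
        subjects, parc, band=config.band, fwhm_mm=config.fwhm_mm,
        thresholds=config.thresholds, n_null=config.n_null, seed=config.seed)
    table.to_tsv(outdir / "features.tsv")
    table.tags_to_tsv(outdir / "feature_tags.tsv")

    summary: dict = {}
    if group_stats:
        summary["group_stats"] = _group_stats_report(subjects, config, outdir)

    model = LateralityModel(table, config.classifier_config())
    results = model.fit(seed=config.seed)

    results.fold_frame().to_csv(outdir / "loocv_folds.tsv", sep="\t", index=False)
    for fold in results.loocv.folds:
        fold.selection.to_yaml(outdir / f"selection_{fold.subject_id}.yaml")
    results.importance.to_tsv(outdir / "importance.tsv")
    results.importance.summary_to_yaml(outdir / "importance_summary.yaml")

    summary.update(results.summary_dict())
    summary["config"] = config.to_dict()
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return results
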