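"""Rank-based, run-normalized feature and sub-category importance.

Within one cross-validation run that selected m features, the most important
feature scores m, the next m-1, ... the least important 1; the scores are
then divided by the run total m(m+1)/2 so every run contributes unit mass.
Aggregating over runs, a feature's importance is the sum of its normalized
scores, a sub-category's importance the sum over its member features, and
percentages are taken against the total mass (= number of runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

__all__ = ["ImportanceReport", "run_scores", "aggregate"]


@dataclass
class ImportanceReport:
    """Aggregated importance over a set of cross-validation runs."""

    feature_scores: pd.Series        # feature -> summed normalized score
    feature_subcategory: pd.Series   # feature -> tag
    subcategory_scores: pd.Series    # tag -> summed score
    percentages: pd.Series           # tag -> share of total mass, in percent
    n_runs: int
    per_run: list[dict]

    @property
    def total_mass(self) -> float:
        return float(self.feature_scores.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subcategory": self.feature_subcategory.loc[self.feature_scores.index],
            "score": self.feature_scores,
        }).rename_axis("feature")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def summary_to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "n_runs": int(self.n_runs),
                    "subcategory_scores": {k: float(v) for k, v
                                           in self.subcategory_scores.items()},
                    "percentages": {k: float(v) for k, v
                                    in self.percentages.items()},
                },
                fh, sort_keys=True)


def run_scores(selected) -> dict[str, float]:
    """Normalized rank scores for one run's ordered selected features.

    With m features, rank j (1 = most important) receives (m - j + 1) /
    (m(m+1)/2); the scores decrease strictly with rank and sum to 1. A run
    that selected a single feature gives it score 1.0 exactly.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("run selected no features")
    if len(set(selected)) != len(selected):
        raise ValueError("duplicate feature names within a run")
    m = len(selected)
    total = m * (m + 1) / 2.0
    return {name: (m - j) / total for j, name in enumerate(selected)}


def aggregate(runs, subcategory) -> ImportanceReport:
    """Sum per-run normalized scores into feature and sub-category importance.

    ``runs`` is a list of per-run score maps (as from :func:`run_scores`);
    ``subcategory`` maps every scored feature name to its tag. Features never
    selected carry no score and are absent from the report.
    """
    subcategory = pd.Series(subcategory)
    scores: dict[str, float] = {}
    for run in runs:
        for name, s in run.items():
            if name not in subcategory.index:
                raise ValueError(f"feature without a sub-category tag: {name}")
            scores[name] = scores.get(name, 0.0) + float(s)
    feature_scores = pd.Series(scores, dtype=float).sort_values(ascending=False)
    tags = subcategory.loc[feature_scores.index]
    subcat_scores = feature_scores.groupby(tags).sum().sort_values(ascending=False)
    n_runs = len(runs)
    pct = subcat_scores / n_runs * 100.0 if n_runs else subcat_scores * 0.0
    return ImportanceReport(
        feature_scores=feature_scores,
        feature_subcategory=tags,
        subcategory_scores=subcat_scores,
        percentages=pct,
        n_runs=n_runs,
        per_run=[dict(r) for r in runs],
    )
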