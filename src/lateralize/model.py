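"""Model/Results facade over the nested LOOCV pipeline.

``LateralityModel`` is built from a :class:`~lateralize.features.FeatureTable`
(or directly from a simulated cohort); ``fit()`` runs the leave-one-patient-
out cross-validation with per-fold random-forest selection and a linear SVM
and returns a ``LateralityResults`` carrying the fold records, the summary
metrics, the importance report and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import ClassifierConfig, LoocvResult, loocv
from .features import SUBCATEGORIES, FeatureTable, build_feature_table
from .importance import ImportanceReport

__all__ = ["LateralityModel", "LateralityResults"]


class LateralityModel:
    """Left-vs-right TLE laterality classifier over a candidate feature space.

    Parameters
    ----------
    features : FeatureTable
        Subjects x features with sub-category tags and L/R labels.
    config : ClassifierConfig, optional
        Nested-selection and SVM settings.
    """

    def __init__(self, features: FeatureTable,
                 config: ClassifierConfig | None = None):
        self.features = features
        self.config = config or ClassifierConfig()

    @classmethod
    def from_cohort(cls, subjects, parcellation, config=None,
                    **feature_kwargs) -> "LateralityModel":
        """Build the model from (bold, confounds, label) triples, running the
        whole feature-extraction stage."""
        table = build_feature_table(subjects, parcellation, **feature_kwargs)
        return cls(table, config=config)

    def fit(self, seed: int = 0) -> "LateralityResults":
        result = loocv(self.features, self.config, seed=seed)
        importance = result.importance(self.features.subcategory)
        return LateralityResults(model=self, loocv=result,
                                 importance=importance, seed=seed)


@dataclass
class LateralityResults:
    """Fitted LOOCV outcome: predictions, metrics, selection and importance."""

    model: LateralityModel
    loocv: LoocvResult
    importance: ImportanceReport
    seed: int = 0

    @property
    def correct_rate(self) -> float:
        return self.loocv.correct_rate

    @property
    def sensitivity(self) -> float:
        return self.loocv.sensitivity

    @property
    def specificity(self) -> float:
        return self.loocv.specificity

    def fold_frame(self) -> pd.DataFrame:
        return self.loocv.to_frame()

    def summary(self) -> str:
        """Plain-text report in the spirit of statsmodels results tables."""
        lv = self.loocv
        n = len(lv.folds)
        lines = [
            "TLE Laterality LOOCV Results",
            "=" * 44,
            f"Subjects:               {n}",
            f"Candidate features:     {self.model.features.n_features}",
            f"Correct rate:           {lv.n_correct}/{n} = {lv.correct_rate:.2%}",
            f"Sensitivity (L):        {lv.sensitivity:.2f}",
            f"Specificity:            {lv.specificity:.2f}",
            f"Selected per fold:      "
            + ", ".join(str(f.selection.n_selected) for f in lv.folds),
            "-" * 44,
            "Sub-category importance (% of total mass):",
        ]
        for tag in SUBCATEGORIES:
            pct = float(self.importance.percentages.get(tag, 0.0))
            lines.append(f"  {tag:<10s} {pct:6.1f}%")
        lines.append("=" * 44)
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        """Deterministic, YAML-serialisable summary of the fit."""
        lv = self.loocv
        return {
            "seed": int(self.seed),
            "n_subjects": len(lv.folds),
            "n_candidate_features": int(self.model.features.n_features),
            "correct_rate": float(lv.correct_rate),
            "sensitivity": float(lv.sensitivity),
            "specificity": float(lv.specificity),
            "n_selected_per_fold": [int(f.selection.n_selected) for f in lv.folds],
            "predictions": {f.subject_id: f.predicted_label for f in lv.folds},
            "subcategory_percentages": {
                k: float(v) for k, v in self.importance.percentages.items()
            },
        }
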