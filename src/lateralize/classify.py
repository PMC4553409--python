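"""Leakage-free leave-one-patient-out cross-validation with a linear SVM.

Everything that looks at the data — the candidate FC filter, the
random-forest selection and the feature standardization statistics — is
computed inside each fold from the training subjects only; the held-out
patient is touched exactly once, at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.svm import SVC

from .features import FeatureTable
from .importance import ImportanceReport, aggregate, run_scores
from .selection import RFConfig, SelectionResult, select_features

__all__ = ["ClassifierConfig", "FoldRecord", "LoocvResult", "evaluate", "loocv"]


@dataclass
class ClassifierConfig:
    """Settings for the nested LOOCV classifier."""

    rf: RFConfig = field(default_factory=RFConfig)
    svm_c: float = 1.0
    candidate_alpha: float = 0.05
    standardize: bool = True
    positive_label: str = "L"


@dataclass
class FoldRecord:
    subject_id: str
    true_label: str
    predicted_label: str
    selection: SelectionResult


@dataclass
class LoocvResult:
    """Per-fold records plus the summary metrics, recomputable from them."""

    folds: list[FoldRecord]
    positive_label: str = "L"

    @property
    def truth(self) -> list[str]:
        return [f.true_label for f in self.folds]

    @property
    def predictions(self) -> list[str]:
        return [f.predicted_label for f in self.folds]

    @property
    def correct_rate(self) -> float:
        return evaluate(self.truth, self.predictions, self.positive_label)[0]

    @property
    def sensitivity(self) -> float:
        return evaluate(self.truth, self.predictions, self.positive_label)[1]

    @property
    def specificity(self) -> float:
        return evaluate(self.truth, self.predictions, self.positive_label)[2]

    @property
    def n_correct(self) -> int:
        return sum(t == p for t, p in zip(self.truth, self.predictions))

    def importance(self, subcategory: pd.Series) -> ImportanceReport:
        runs = [run_scores(f.selection.selected) for f in self.folds]
        return aggregate(runs, subcategory)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [f.subject_id for f in self.folds],
            "true_label": self.truth,
            "predicted_label": self.predictions,
            "n_features": [f.selection.n_selected for f in self.folds],
        })


def evaluate(truth, predicted, positive: str = "L") -> tuple[float, float, float]:
    """(correct_rate, sensitivity, specificity) for two label sequences.

    Sensitivity is the recall of the positive class (left TLE by default),
    specificity the recall of the other class. Degenerate denominators
    (a class absent from truth) yield NaN for that metric.
    """
    truth = list(truth)
    predicted = list(predicted)
    if not truth or len(truth) != len(predicted):
        raise ValueError("need two equal-length, nonempty label sequences")
    correct = sum(t == p for t, p in zip(truth, predicted))
    tp = sum(1 for t, p in zip(truth, predicted) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(truth, predicted) if t == positive and p != positive)
    tn = sum(1 for t, p in zip(truth, predicted) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(truth, predicted) if t != positive and p == positive)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return correct / len(truth), sens, spec


def _fc_candidate_names(train: FeatureTable, alpha: float) -> set[str]:
    """FC features whose training z-values pass the one-sample t-test vs 0."""
    fc_names = train.features_of("FC")
    if not fc_names:
        return set()
    vals = train.values[fc_names].to_numpy(dtype=float)
    n = vals.shape[0]
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * _stats.t.sf(np.abs(t), df=n - 1)
    sig = p < alpha
    zero_var = sd == 0
    sig[zero_var] = mean[zero_var] != 0
    sig[np.isnan(vals).any(axis=0)] = False
    return {name for name, s in zip(fc_names, sig) if s}


def _fit_fold(train: FeatureTable, test_row: pd.Series,
              config: ClassifierConfig, fold_seed: int
              ) -> tuple[str, SelectionResult]:
    if train.labels.nunique() < 2:
        raise ValueError("training fold is single-class; cannot fit")
    fc_keep = _fc_candidate_names(train, config.candidate_alpha)
    keep = [name for name, tag in train.subcategory.items()
            if tag != "FC" or name in fc_keep]
    fold_table = train.select_features(keep)
    selection = select_features(fold_table, rf=config.rf, seed=fold_seed)

    X_train = fold_table.values[selection.selected].to_numpy(dtype=float)
    x_test = test_row[selection.selected].to_numpy(dtype=float)[None, :]
    if config.standardize:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        x_test = (x_test - mu) / sd
    svm = SVC(kernel="linear", C=config.svm_c)
    svm.fit(X_train, train.labels.to_numpy())
    pred = str(svm.predict(x_test)[0])
    return pred, selection


def loocv(table: FeatureTable, config: ClassifierConfig | None = None,
          seed: int = 0) -> LoocvResult:
    """Leave-one-patient-out cross-validation over the feature table.

    One fold per subject; candidate filtering, selection and standardization
    statistics are recomputed from the training subjects of each fold.
    """
    config = config or ClassifierConfig()
    if table.labels.value_counts().min() < 2:
        raise ValueError("need at least 2 subjects per class for LOOCV")
    folds = []
    for fold_idx, sid in enumerate(table.values.index):
        train_ids = [s for s in table.values.index if s != sid]
        train = table.subset_subjects(train_ids)
        fold_seed = seed + 10_000 * (fold_idx + 1)
        pred, selection = _fit_fold(train, table.values.loc[sid], config, fold_seed)
        folds.append(FoldRecord(subject_id=str(sid),
                                true_label=str(table.labels.loc[sid]),
                                predicted_label=pred,
                                selection=selection))
    return LoocvResult(folds=folds, positive_label=config.positive_label)
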