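"""Cohort splitting, logistic-regression training, evaluation, candidates.

The classifier is an L2-regularised logistic regression on one topological
feature (node degree by default), with the aggressive phenotype as the
positive class. Features are used on their raw scale unless standardisation
is requested; when it is, the learned coefficients are folded back onto the
raw scale so the stored model is self-contained.

Candidate loci are ranked by the absolute value of their coefficient; a
positive coefficient means a larger value of the feature increases the
predicted probability of the aggressive phenotype.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, balanced_accuracy_score,
                             confusion_matrix, f1_score, roc_auc_score, roc_curve)

from .exceptions import ConvergenceError, ValidationError
from .io_qc import validate_phenotypes
from .topology import FeatureMatrix

__all__ = ["split_cohorts", "TrainedClassifier", "train", "EvaluationReport",
           "evaluate", "candidate_loci"]

POSITIVE_LABEL = "aggressive"
NEGATIVE_LABEL = "non_aggressive"


def split_cohorts(phenotypes: pd.DataFrame, n_modeling: int, seed: int = 0) -> pd.DataFrame:
    """Assign modeling / training roles among the non-evaluation samples.

    ``n_modeling`` randomly chosen non-aggressive samples become the
    modeling (baseline) cohort; the remaining non-aggressive samples plus
    all aggressive samples of the source dataset become the training set.
    Samples already tagged ``evaluation`` are left untouched.
    """
    phen = validate_phenotypes(phenotypes).copy()
    if "cohort" in phen.columns:
        pool = phen.index[phen["cohort"] != "evaluation"]
    else:
        phen["cohort"] = ""
        pool = phen.index
    neg = [s for s in pool if phen.at[s, "label"] == NEGATIVE_LABEL]
    pos = [s for s in pool if phen.at[s, "label"] == POSITIVE_LABEL]
    if n_modeling > len(neg):
        raise ValidationError(
            f"n_modeling ({n_modeling}) exceeds the {len(neg)} available "
            f"non-aggressive samples")
    if n_modeling == len(neg):
        raise ValidationError(
            "n_modeling would leave no non-aggressive samples for training")
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(np.array(neg, dtype=object))[:n_modeling]
    phen.loc[list(chosen), "cohort"] = "modeling"
    rest = [s for s in neg if s not in set(chosen)]
    phen.loc[rest + pos, "cohort"] = "training"
    return phen


def _as_binary(labels, index) -> np.ndarray:
    lab = pd.Series(labels)
    if set(index) <= set(lab.index):
        lab = lab.reindex(index)
    if len(lab) != len(index):
        raise ValidationError("labels do not align with the feature rows")
    unknown = set(lab.unique()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if unknown:
        raise ValidationError(f"unknown labels: {sorted(map(str, unknown))}")
    return (lab == POSITIVE_LABEL).to_numpy()


@dataclass
class TrainedClassifier:
    """Raw-scale coefficients of the fitted logistic regression."""

    coef: pd.Series           # indexed by locus, panel order
    intercept: float
    settings: dict = field(default_factory=dict)
    seed: int = 0
    training_samples: tuple = ()
    feature_name: str = "degree"

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.coef.index].to_numpy()
        return x @ self.coef.to_numpy() + self.intercept

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """P(aggressive) per sample."""
        z = self.decision_function(features)
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self) -> str:
        return json.dumps({
            "schema": 1,
            "feature_name": self.feature_name,
            "loci": self.coef.index.tolist(),
            "coef": self.coef.to_numpy().tolist(),
            "intercept": self.intercept,
            "settings": self.settings,
            "seed": self.seed,
            "training_samples": list(self.training_samples),
        }, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        d = json.loads(text)
        return cls(
            coef=pd.Series(d["coef"], index=pd.Index(d["loci"], name="locus")),
            intercept=float(d["intercept"]),
            settings=d.get("settings", {}),
            seed=int(d.get("seed", 0)),
            training_samples=tuple(d.get("training_samples", ())),
            feature_name=d.get("feature_name", "degree"),
        )


def train(features: FeatureMatrix | pd.DataFrame, labels, C: float = 1.0,
          standardize: bool = False, seed: int = 0,
          max_iter: int = 10000) -> TrainedClassifier:
    """Fit the L2 logistic regression on training-cohort features."""
    frame = features.frame if isinstance(features, FeatureMatrix) else features
    feature_name = features.name if isinstance(features, FeatureMatrix) else "feature"
    y = _as_binary(labels, frame.index)
    if y.all() or not y.any():
        raise ValidationError("training labels contain a single class")
    x = frame.to_numpy(dtype=np.float64)
    mu = np.zeros(x.shape[1])
    sigma = np.ones(x.shape[1])
    if standardize:
        mu = x.mean(axis=0)
        sigma = x.std(axis=0)
        sigma[sigma == 0] = 1.0
        x = (x - mu) / sigma

    # default penalty is the L2 ridge; spelling it out is deprecated in sklearn
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter,
                             random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(x, y)
        except ConvergenceWarning as exc:
            raise ConvergenceError(
                f"logistic regression did not converge within {max_iter} "
                f"iterations: {exc}") from exc

    raw_coef = clf.coef_[0] / sigma
    raw_intercept = float(clf.intercept_[0] - (clf.coef_[0] * mu / sigma).sum())
    return TrainedClassifier(
        coef=pd.Series(raw_coef, index=pd.Index(frame.columns, name="locus")),
        intercept=raw_intercept,
        settings={"C": C, "standardize": standardize, "penalty": "l2",
                  "solver": "lbfgs"},
        seed=seed,
        training_samples=tuple(frame.index),
        feature_name=feature_name,
    )


@dataclass
class EvaluationReport:
    """Held-out classification metrics (aggressive = positive class)."""

    accuracy: float
    balanced_accuracy: float
    f1: float
    roc_auc: float
    confusion: np.ndarray        # rows true (neg, pos), cols predicted
    probabilities: pd.Series     # P(aggressive) per evaluation sample
    roc_points: pd.DataFrame     # fpr, tpr, threshold

    def to_json(self) -> str:
        return json.dumps({
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "confusion": self.confusion.tolist(),
            "probabilities": {k: float(v) for k, v in self.probabilities.items()},
        }, sort_keys=True, indent=1)

    def __str__(self) -> str:
        (tn, fp), (fn, tp) = self.confusion
        return (
            "Evaluation (positive class = aggressive)\n"
            f"  samples            {len(self.probabilities)}\n"
            f"  accuracy           {self.accuracy:.3f}\n"
            f"  balanced accuracy  {self.balanced_accuracy:.3f}\n"
            f"  F1                 {self.f1:.3f}\n"
            f"  ROC-AUC            {self.roc_auc:.3f}\n"
            f"  confusion          TN={tn} FP={fp} FN={fn} TP={tp}\n"
        )


def evaluate(model: TrainedClassifier, features: FeatureMatrix | pd.DataFrame,
             labels) -> EvaluationReport:
    """Score held-out samples; errors if they overlap the training cohort."""
    frame = features.frame if isinstance(features, FeatureMatrix) else features
    overlap = set(frame.index) & set(model.training_samples)
    if overlap:
        raise ValidationError(
            f"evaluation samples overlap the training cohort: {sorted(overlap)[:5]}")
    y = _as_binary(labels, frame.index)
    probs = model.predict_proba(frame)
    pred = probs >= 0.5
    if y.all() or not y.any():
        raise ValidationError("evaluation labels contain a single class")
    fpr, tpr, thr = roc_curve(y, probs)
    return EvaluationReport(
        accuracy=float(accuracy_score(y, pred)),
        balanced_accuracy=float(balanced_accuracy_score(y, pred)),
        f1=float(f1_score(y, pred)),
        roc_auc=float(roc_auc_score(y, probs)),
        confusion=confusion_matrix(y, pred, labels=[False, True]),
        probabilities=pd.Series(probs, index=frame.index, name="p_aggressive"),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
    )


def candidate_loci(model: TrainedClassifier, annotation: pd.DataFrame | None = None,
                   top_fraction: float = 0.05) -> pd.DataFrame:
    """The ceil(top_fraction * panel) loci with largest |coefficient|.

    Ties in |coefficient| at the boundary break lexicographically by locus
    id, so the count is exact and deterministic. Annotation columns (gene,
    enhancer, tfbs) are joined when an annotation covering the panel is
    supplied.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValidationError(f"top_fraction must lie in (0, 1], got {top_fraction!r}")
    coef = model.coef
    n_top = math.ceil(top_fraction * len(coef))
    order = sorted(coef.index, key=lambda l: (-abs(coef[l]), l))
    chosen = order[:n_top]
    table = pd.DataFrame({
        "coefficient": coef[chosen],
        "rank": np.arange(1, n_top + 1),
        "direction": ["increases probability" if coef[l] > 0
                      else "decreases probability" for l in chosen],
    }, index=pd.Index(chosen, name="locus"))
    if annotation is not None:
        missing = [l for l in chosen if l not in annotation.index]
        if missing:
            raise ValidationError(
                f"candidate loci missing from annotation: {missing[:10]}")
        table = table.join(annotation.loc[chosen, ["gene", "enhancer", "tfbs"]])
    return table
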