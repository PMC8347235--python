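"""Platt-calibrated random-forest bioactivity filter.

The first stage of each per-target funnel: a 100-tree random forest on
radius-2 Morgan fingerprints, trained on curated actives versus MW-matched
decoys, with output vote fractions mapped to probabilities by Platt
(sigmoid) scaling.  The filter is deliberately permissive — compounds with
a calibrated probability of activity below 20% are discarded, everything
else continues down the funnel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from mmpscreen.core_chem import MoleculeRecord, morgan_fingerprint

__all__ = [
    "RFConfig",
    "ClassifierMetrics",
    "CalibratedModel",
    "compute_metrics",
    "train_calibrated_rf",
    "cross_validate",
    "apply_probability_filter",
]


@dataclass(frozen=True)
class RFConfig:
    """Training configuration for the calibrated random forest."""

    n_trees: int = 100
    fp_radius: int = 2
    fp_nbits: int = 2048
    probability_threshold: float = 0.20
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.probability_threshold < 1:
            raise ValueError("probability_threshold must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class ClassifierMetrics:
    """The nine confusion-matrix statistics reported for every filter.

    All are dimensionless fractions; MCC lies in [-1, 1], the rest in
    [0, 1].  Ratios with a zero denominator are NaN, never silently 0.
    """

    sensitivity: float
    specificity: float
    precision: float
    fall_out: float
    false_negative_rate: float
    false_discovery_rate: float
    accuracy: float
    f1_score: float
    matthews_cc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "fall_out": self.fall_out,
            "false_negative_rate": self.false_negative_rate,
            "false_discovery_rate": self.false_discovery_rate,
            "accuracy": self.accuracy,
            "f1_score": self.f1_score,
            "matthews_cc": self.matthews_cc,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassifierMetrics:
    """Confusion-matrix statistics from raw counts.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/total,
    F1 = 2TP/(2TP+FP+FN),
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Fall-out, false-negative rate and false-discovery rate are the
    complements of specificity, sensitivity and precision.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    acc = (tp + tn) / total
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    return ClassifierMetrics(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        fall_out=1.0 - spec,
        false_negative_rate=1.0 - sens,
        false_discovery_rate=1.0 - prec,
        accuracy=acc,
        f1_score=f1,
        matthews_cc=mcc,
    )


@dataclass
class CalibratedModel:
    """A trained forest plus its Platt calibration map and metadata."""

    estimator: CalibratedClassifierCV
    config: RFConfig
    n_actives: int
    n_decoys: int
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        """Calibrated probability of activity for each record."""
        X = _feature_matrix(records, self.config)
        return self.estimator.predict_proba(X)[:, 1]

    def raw_vote_fraction(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        """Uncalibrated forest vote fraction (pre-sigmoid score)."""
        X = _feature_matrix(records, self.config)
        forest = self.estimator.calibrated_classifiers_[0].estimator
        return forest.predict_proba(X)[:, 1]


def _feature_matrix(
    records: Sequence[MoleculeRecord], config: RFConfig
) -> np.ndarray:
    return np.stack(
        [
            morgan_fingerprint(
                r, radius=config.fp_radius, nbits=config.fp_nbits
            ).bits
            for r in records
        ]
    )


def _build_estimator(config: RFConfig) -> CalibratedClassifierCV:
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    # ensemble=False keeps a single forest and a single sigmoid, so the
    # calibrated probability is an exactly monotone map of the vote fraction
    return CalibratedClassifierCV(
        forest, method="sigmoid", cv=config.cv_folds, ensemble=False
    )


def train_calibrated_rf(
    actives: Sequence[MoleculeRecord],
    decoys: Sequence[MoleculeRecord],
    config: RFConfig | None = None,
) -> CalibratedModel:
    """Train the forest and fit the Platt sigmoid.

    The sigmoid is fitted on cross-validated out-of-fold scores to avoid
    calibrating on scores the forest has memorised.  Reproducible for a
    fixed :attr:`RFConfig.seed`.
    """
    config = config or RFConfig()
    if len(actives) == 0 or len(decoys) == 0:
        raise ValueError("both actives and decoys must be non-empty")
    records = list(actives) + list(decoys)
    y = np.array([1] * len(actives) + [0] * len(decoys))
    X = _feature_matrix(records, config)
    est = _build_estimator(config)
    est.fit(X, y)
    return CalibratedModel(
        estimator=est,
        config=config,
        n_actives=len(actives),
        n_decoys=len(decoys),
    )


def cross_validate(
    actives: Sequence[MoleculeRecord],
    decoys: Sequence[MoleculeRecord],
    config: RFConfig | None = None,
) -> ClassifierMetrics:
    """Stratified k-fold cross-validation of the calibrated filter.

    Each fold trains on (k-1)/k of the compounds and evaluates on the held
    fold (80%/20% at the default k = 5); predicted class is probability
    >= 0.5.  Per-fold metrics are averaged.  Fold assignment is seeded.
    """
    config = config or RFConfig()
    k = config.cv_folds
    if len(actives) < k or len(decoys) < k:
        raise ValueError(
            f"each class needs >= {k} members for {k}-fold CV "
            f"(got {len(actives)} actives, {len(decoys)} decoys)"
        )
    records = list(actives) + list(decoys)
    y = np.array([1] * len(actives) + [0] * len(decoys))
    X = _feature_matrix(records, config)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_metrics = []
    for train_idx, test_idx in skf.split(X, y):
        est = _build_estimator(config)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[test_idx])[:, 1]
        pred = (proba >= 0.5).astype(int)
        truth = y[test_idx]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        fold_metrics.append(compute_metrics(tp, fp, tn, fn))
    means = {
        key: float(np.mean([m.as_dict()[key] for m in fold_metrics]))
        for key in fold_metrics[0].as_dict()
    }
    return ClassifierMetrics(**means)


def apply_probability_filter(
    model: CalibratedModel,
    library: Sequence[MoleculeRecord],
    threshold: float | None = None,
) -> list[tuple[MoleculeRecord, float]]:
    """Keep library compounds with calibrated probability >= threshold.

    The default threshold (0.20) discards only compounds with a
    less-than-20% probability of being active: exactly 0.20 survives.
    Returns ``(record, probability)`` pairs in input order.
    """
    if threshold is None:
        threshold = model.config.probability_threshold
    if len(library) == 0:
        return []
    proba = model.predict_proba(library)
    return [
        (rec, float(p)) for rec, p in zip(library, proba) if p >= threshold
    ]
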