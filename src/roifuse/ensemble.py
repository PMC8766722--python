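"""Weighted late fusion of per-modality classifier probabilities.

The ensemble prediction for subject *i* is the convex combination
``Y_i = sum_k c_k * y_ki`` of the per-modality AD probabilities ``y_ki``,
with weights ``c_k`` in [0, 1] summing to one.  Equal weights (1/2 for a
pair, 1/3 for a triple) are the default scheme; all subsets of size >= 2
can be enumerated and compared against the single-modality baselines on
the same joined subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .classify import (ModalityModel, confusion_metrics, predict_label,
                       predict_probability, roc_and_auc)
from .errors import ConfigError, DataError
from .tables import FeatureTable, join_subjects

__all__ = [
    "EnsembleWeights",
    "FusionResult",
    "fuse_probabilities",
    "evaluate_combination",
    "enumerate_combinations",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class EnsembleWeights:
    """Convex per-modality coefficients: each in [0, 1], summing to one."""

    modalities: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "modalities", tuple(self.modalities))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.modalities) != len(self.weights) or not self.modalities:
            raise ConfigError("EnsembleWeights needs one weight per modality")
        if len(set(self.modalities)) != len(self.modalities):
            raise ConfigError("EnsembleWeights.modalities must be unique")
        if any(w < 0.0 or w > 1.0 for w in self.weights):
            raise ConfigError("EnsembleWeights.weights must lie in [0, 1]")
        if abs(sum(self.weights) - 1.0) > _WEIGHT_TOL:
            raise ConfigError("EnsembleWeights.weights must sum to 1")

    @classmethod
    def equal(cls, modalities) -> "EnsembleWeights":
        modalities = tuple(modalities)
        k = len(modalities)
        return cls(modalities, tuple([1.0 / k] * k))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.modalities, self.weights))


@dataclass(frozen=True)
class FusionResult:
    """Fused probabilities, hard labels, contributors and metrics."""

    subject_ids: tuple[str, ...]
    true_labels: np.ndarray = field(repr=False)
    fused_probability: np.ndarray = field(repr=False)
    fused_label: np.ndarray = field(repr=False)
    per_modality_probability: dict[str, np.ndarray] = field(repr=False)
    weights: EnsembleWeights
    metrics: dict[str, float]
    auc: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "modalities": list(self.weights.modalities),
            "weights": list(self.weights.weights),
            "n_subjects": len(self.subject_ids),
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "auc": float(self.auc),
            "fused_probability": [float(p) for p in self.fused_probability],
            "subject_ids": list(self.subject_ids),
        }


def fuse_probabilities(probabilities: dict[str, np.ndarray],
                       weights: EnsembleWeights) -> np.ndarray:
    """``Y_i = sum_k c_k y_ki`` over modalities; AD when Y_i >= 0.5."""
    missing = [m for m in weights.modalities if m not in probabilities]
    if missing:
        raise DataError(f"missing probabilities for modalities {missing}")
    arrays = [np.asarray(probabilities[m], dtype=float) for m in weights.modalities]
    n = arrays[0].shape[0]
    if any(a.shape != (n,) for a in arrays):
        raise DataError("per-modality probability vectors must cover the same subjects")
    fused = np.zeros(n)
    for w, a in zip(weights.weights, arrays):
        fused += w * a
    return fused


def evaluate_combination(models: dict[str, ModalityModel],
                         tables: dict[str, FeatureTable],
                         weights: EnsembleWeights) -> FusionResult:
    """Score each modality's model, fuse with the weights, compute metrics.

    Subjects are inner-joined across the involved modality tables; labels
    must agree.  Raises on an empty intersection.
    """
    for m in weights.modalities:
        if m not in models:
            raise DataError(f"no model for modality {m!r}")
        if m not in tables:
            raise DataError(f"no table for modality {m!r}")
    involved = {m: tables[m] for m in weights.modalities}
    joined = join_subjects(involved)
    probs: dict[str, np.ndarray] = {}
    labels = None
    for m in weights.modalities:
        sub = tables[m].take_subject_ids(joined)
        probs[m] = predict_probability(models[m], sub)
        labels = sub.labels
    fused = fuse_probabilities(probs, weights)
    pred = predict_label(fused)
    metrics = confusion_metrics(labels, pred)
    fpr, tpr, auc = roc_and_auc(labels, fused)
    return FusionResult(tuple(joined), labels, fused, pred, probs, weights,
                        metrics, auc, fpr, tpr)


def enumerate_combinations(models: dict[str, ModalityModel],
                           tables: dict[str, FeatureTable]):
    """Equal-weight fusion of every modality subset of size >= 2.

    Subjects are joined across *all* modalities once, so every combination
    and every single-modality baseline is evaluated on the same cohort.

    Returns ``(singles, combos)``: single-modality baselines keyed by
    modality name, and equal-weight fusion results keyed by the modality
    tuple (three pairs and one triple for three modalities).
    """
    names = sorted(models)
    if len(names) < 2:
        raise DataError("combination enumeration needs >= 2 models")
    joined = join_subjects({m: tables[m] for m in names})
    joined_tables = {m: tables[m].take_subject_ids(joined) for m in names}
    singles = {m: evaluate_combination(models, joined_tables,
                                       EnsembleWeights((m,), (1.0,)))
               for m in names}
    combos = {}
    for k in range(2, len(names) + 1):
        for subset in combinations(names, k):
            combos[subset] = evaluate_combination(
                models, joined_tables, EnsembleWeights.equal(subset))
    return singles, combos
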