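"""Low-level features, SVM detection on sparse codes, and evaluation metrics.

The high-level feature of a candidate is its nonnegative elastic-net code
over the learned dictionary — the coefficient vector directly expresses the
candidate's similarity to mitotic vs nonmitotic basis patterns — so a
plain max-margin linear classifier on codes suffices for detection.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "LabeledFeature",
    "DetectionMetrics",
    "SVMConfig",
    "MitosisClassifier",
    "raw_feature",
    "get_feature_extractor",
    "register_feature_extractor",
    "train_classifier",
    "evaluate",
    "f_score",
]

MITOTIC, NONMITOTIC = "mitotic", "nonmitotic"


@dataclass
class LabeledFeature:
    sample_id: int
    vector: np.ndarray
    label: str  # MITOTIC | NONMITOTIC


def raw_feature(patch: np.ndarray) -> np.ndarray:
    """Pixel-wise intensity feature: intensities concatenated in raster order."""
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("patch must be nonempty")
    return patch.ravel(order="C").copy()


# Pluggable low-level feature extractors; only "raw" ships, others mountable.
_FEATURE_EXTRACTORS = {"raw": raw_feature}


def register_feature_extractor(name: str, fn) -> None:
    _FEATURE_EXTRACTORS[name] = fn


def get_feature_extractor(name: str):
    try:
        return _FEATURE_EXTRACTORS[name]
    except KeyError:
        raise KeyError(
            f"unknown feature extractor {name!r}; registered: {sorted(_FEATURE_EXTRACTORS)}"
        ) from None


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")


def _codes_to_matrix(codes) -> np.ndarray:
    rows = [np.asarray(getattr(c, "w", c), dtype=float).ravel() for c in codes]
    return np.stack(rows)


@dataclass
class MitosisClassifier:
    """Linear max-margin classifier over sparse-code features."""

    svm: SVC
    config: SVMConfig
    n_features: int

    def predict(self, codes) -> list[str]:
        X = _codes_to_matrix(codes)
        return [MITOTIC if y == 1 else NONMITOTIC for y in self.svm.predict(X)]

    def decision_function(self, codes) -> np.ndarray:
        return self.svm.decision_function(_codes_to_matrix(codes))

    def save(self, model_path, meta_path) -> None:
        with open(model_path, "wb") as fh:
            pickle.dump(self.svm, fh)
        with open(meta_path, "w") as fh:
            json.dump(
                {"format_version": 1, "n_features": self.n_features,
                 "C": self.config.C, "class_weight": self.config.class_weight},
                fh, indent=2,
            )

    @classmethod
    def load(cls, model_path, meta_path) -> "MitosisClassifier":
        with open(model_path, "rb") as fh:
            svm = pickle.load(fh)
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(
            svm=svm,
            config=SVMConfig(C=meta["C"], class_weight=meta["class_weight"]),
            n_features=meta["n_features"],
        )


def train_classifier(codes, labels, svm_config: SVMConfig | None = None) -> MitosisClassifier:
    """Train the linear SVM on code vectors (labels: mitotic/nonmitotic)."""
    if svm_config is None:
        svm_config = SVMConfig()
    X = _codes_to_matrix(codes)
    y = np.array([1 if lab == MITOTIC else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one sample of each class")
    svm = SVC(kernel="linear", C=svm_config.C, class_weight=svm_config.class_weight)
    svm.fit(X, y)
    return MitosisClassifier(svm=svm, config=svm_config, n_features=X.shape[1])


def f_score(precision: float, recall: float) -> float:
    """F1 = 2 P R / (P + R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)
    accuracy: float = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.degenerate = False
        if self.tp + self.fp > 0:
            self.precision = self.tp / (self.tp + self.fp)
        else:
            self.precision, self.degenerate = 0.0, True
        if self.tp + self.fn > 0:
            self.recall = self.tp / (self.tp + self.fn)
        else:
            self.recall, self.degenerate = 0.0, True
        self.f1 = f_score(self.precision, self.recall)
        total = self.tp + self.fp + self.fn + self.tn
        if total > 0:
            self.accuracy = (self.tp + self.tn) / total
        else:
            self.accuracy, self.degenerate = 0.0, True

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
            "degenerate": self.degenerate,
        }


def evaluate(predictions, truth) -> DetectionMetrics:
    """Confusion counts and Precision/Recall/F1/Accuracy for label lists."""
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError(
            f"predictions ({len(predictions)}) and truth ({len(truth)}) lengths differ"
        )
    tp = sum(1 for p, t in zip(predictions, truth) if p == MITOTIC and t == MITOTIC)
    fp = sum(1 for p, t in zip(predictions, truth) if p == MITOTIC and t != MITOTIC)
    fn = sum(1 for p, t in zip(predictions, truth) if p != MITOTIC and t == MITOTIC)
    tn = sum(1 for p, t in zip(predictions, truth) if p != MITOTIC and t != MITOTIC)
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
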