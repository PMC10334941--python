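"""Scoring and agreement statistics.

Per-head accuracy and ROC AUC for the disease and the three checklist
features, mean/SD aggregation across cross-validation folds, and the
annotation-protocol statistics: Cohen's kappa between annotator pairs and
the third-annotator majority vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .model import MELANOMA, ModelState

__all__ = [
    "EvalReport",
    "AnnotationSet",
    "accuracy",
    "auc",
    "fold_aggregate",
    "cohen_kappa",
    "majority_vote",
    "evaluate_model",
]

FEATURE_NAMES = ("asymmetry", "network", "bluewhite")


@dataclass
class EvalReport:
    """Per-head metrics of one model on one evaluation set.

    ``per_head`` maps head name (disease + the three features) to
    ``{"accuracy": ..., "auc": ...}``; an AUC that is undefined (single
    class present) is NaN.  Fold statistics use the sample SD (n−1).
    """

    per_head: dict
    n_samples: int
    config_hash: str = ""
    fold_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for head, m in self.per_head.items():
            a = m.get("accuracy")
            if a is not None and not np.isnan(a) and not 0.0 <= a <= 1.0:
                raise ValueError(f"accuracy for {head} outside [0, 1]: {a}")


@dataclass
class AnnotationSet:
    """One annotator's checklist decisions over an aligned image list."""

    annotator_id: str
    image_ids: list
    flags: np.ndarray  # (n_images, 3) binary

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags)
        if self.flags.ndim != 2 or self.flags.shape[1] != 3:
            raise ValueError("flags must be (n_images, 3)")
        if not np.all((self.flags == 0) | (self.flags == 1)):
            raise ValueError("flags must be binary")
        if len(self.image_ids) != self.flags.shape[0]:
            raise ValueError("image_ids and flags must align")


def accuracy(predictions, truth) -> float:
    """Fraction of exact matches between two aligned label vectors."""
    p = np.asarray(predictions)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("predictions and truth must have equal length")
    if p.size == 0:
        raise ValueError("empty label vectors")
    return float((p == t).mean())


def auc(scores, truth) -> float:
    """Mann-Whitney ROC area: P(random positive outscores random negative).

    Ties count half.  With a single class in ``truth`` the area is
    undefined: NaN is returned with a warning.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(truth)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    if np.unique(t).size < 2:
        warnings.warn("AUC undefined: only one class present; reporting NaN")
        return float("nan")
    return float(roc_auc_score(t, s))


def fold_aggregate(per_fold_metrics) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1 divisor) across folds."""
    v = np.asarray(per_fold_metrics, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two folds to aggregate")
    return float(v.mean()), float(v.std(ddof=1))


def cohen_kappa(a: AnnotationSet, b: AnnotationSet, feature: str | None = None) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e) between two annotators.

    ``feature`` selects one checklist flag by name; ``None`` pools the
    decisions of all three features into one binary agreement problem.
    Degenerate marginals (chance agreement 1) yield NaN with a warning.
    """
    if a.image_ids != b.image_ids:
        raise ValueError("annotation sets must cover the same images in order")
    if feature is None:
        x, y = a.flags.ravel(), b.flags.ravel()
    else:
        try:
            k = FEATURE_NAMES.index(feature)
        except ValueError:
            raise ValueError(f"unknown feature {feature!r}; valid: {FEATURE_NAMES}")
        x, y = a.flags[:, k], b.flags[:, k]
    po = float((x == y).mean())
    pe = 0.0
    for v in (0, 1):
        pe += float((x == v).mean()) * float((y == v).mean())
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            warnings.warn("kappa undefined: degenerate identical marginals; NaN")
            return float("nan")
        return float(cohen_kappa_score(x, y))
    return float(cohen_kappa_score(x, y))


def majority_vote(a, b, c=None):
    """Consensus flags from two or three aligned annotators.

    Where the first two agree the third is ignored (the protocol only
    consults a third annotator on disagreement).  Disagreement without a
    third value leaves the image unresolved (-1).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("annotator vectors must align")
    out = np.where(a == b, a, -1)
    disagree = a != b
    if c is not None:
        c = np.asarray(c)
        if c.shape != a.shape:
            raise ValueError("annotator vectors must align")
        out = np.where(disagree, c, out)
    return out


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def evaluate_model(state: ModelState, dataset, branch: str = "teacher",
                   batch: int = 256, config_hash: str = "") -> EvalReport:
    """Score one model branch on an annotated dataset, per head.

    The teacher branch is evaluated by default — its averaged weights are
    the mean-teacher scheme's final predictor; ``branch="student"`` scores
    the raw student.  Disease predictions are the softmax argmax; feature
    predictions threshold the sigmoid probability at 0.5, while AUC uses
    the raw probabilities.
    """
    if branch not in ("teacher", "student"):
        raise ValueError("branch must be 'teacher' or 'student'")
    net = state.teacher if branch == "teacher" else state.student
    zd_parts, zf_parts = [], []
    for i in range(0, len(dataset), batch):
        out = net.forward(dataset.images[i : i + batch], train=False)
        zd_parts.append(out.disease_logits)
        zf_parts.append(out.feature_logits)
    zd = np.concatenate(zd_parts)
    zf = np.concatenate(zf_parts)

    e = zd - zd.max(axis=1, keepdims=True)
    p_mel = np.exp(e[:, MELANOMA]) / np.exp(e).sum(axis=1)
    per_head = {
        "disease": {
            "accuracy": accuracy(zd.argmax(axis=1), dataset.disease),
            "auc": auc(p_mel, dataset.disease),
        }
    }
    truth = dataset.features
    probs = _sigmoid(zf)
    for k, name in enumerate(FEATURE_NAMES):
        per_head[name] = {
            "accuracy": accuracy((probs[:, k] >= 0.5).astype(int),
                                 truth[:, k].astype(int)),
            "auc": auc(probs[:, k], truth[:, k].astype(int)),
        }
    return EvalReport(per_head=per_head, n_samples=len(dataset),
                      config_hash=config_hash)
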