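"""Loss terms of the knowledge-integrated objective.

Four terms are combined into one training objective:

* **DSL** — disease supervised loss: softmax cross-entropy on the two-way
  melanoma / melanocytic-nevus head.
* **FSL** — feature supervised loss: per-feature sigmoid binary cross-entropy
  on the three checklist heads (asymmetry, atypical network, blue-white
  structure), with optional per-feature weights.
* **RL** — ranking loss: a pairwise cross-entropy on melanoma-logit
  differences that pushes the model's disease ordering to match the 3-point
  checklist score ordering (higher score => more melanoma-like).
* **CL** — consistency loss: mean squared difference between the student's
  and the EMA teacher's predicted distributions.

Every loss returns ``(value, gradient-with-respect-to-its-logits)`` so the
training loop can feed the analytic gradients straight into the network's
backward pass.  Values and gradients are plain numpy; no autograd engine is
involved, which keeps the terms independently checkable against brute-force
oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChecklistAnnotation",
    "LossWeights",
    "checklist_score",
    "ranking_target",
    "ranking_loss",
    "disease_supervised_loss",
    "feature_supervised_loss",
    "consistency_loss",
    "combined_loss",
]


@dataclass(frozen=True)
class ChecklistAnnotation:
    """One image's 3-point checklist: three binary flags and their score.

    The score is the number of flags present (0-3); a total above 2 is the
    checklist's cue for malignancy.
    """

    asymmetry: int
    atypical_network: int
    blue_white: int

    def __post_init__(self) -> None:
        for name in ("asymmetry", "atypical_network", "blue_white"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")

    @property
    def score(self) -> int:
        return self.asymmetry + self.atypical_network + self.blue_white

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.asymmetry, self.atypical_network, self.blue_white], dtype=np.float64
        )


@dataclass(frozen=True)
class LossWeights:
    """Balancing coefficients for the four loss terms.

    ``feature_weights`` re-weights the three checklist features inside the
    FSL (the asymmetry-emphasis ablation sets it to (2, 1, 1)); the weights
    are renormalized to sum to 3 so that (1, 1, 1) is the plain unweighted
    case.
    """

    lambda_dsl: float = 1.0
    lambda_fsl: float = 1.0
    lambda_rl: float = 1.0
    lambda_cl: float = 1.0
    feature_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        lams = (self.lambda_dsl, self.lambda_fsl, self.lambda_rl, self.lambda_cl)
        if any(l < 0 for l in lams):
            raise ValueError("loss coefficients must be nonnegative")
        if all(l == 0 for l in lams):
            raise ValueError("at least one loss coefficient must be positive")
        if any(w < 0 for w in self.feature_weights):
            raise ValueError("feature weights must be nonnegative")


def checklist_score(annotation: ChecklistAnnotation) -> int:
    """Sum of the three binary checklist flags, in 0-3."""
    return annotation.score


def ranking_target(s_i: int, s_j: int) -> float:
    """Desired posterior P̄_ij for a pair of checklist scores.

    1 if ``s_i > s_j`` (i should rank above j), 0 if ``s_i < s_j``, and 0.5
    on ties — the target of the pairwise cross-entropy below.
    """
    for s in (s_i, s_j):
        if not 0 <= s <= 3:
            raise ValueError(f"checklist score must be in 0..3, got {s}")
    if s_i > s_j:
        return 1.0
    if s_i < s_j:
        return 0.0
    return 0.5


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def ranking_loss(
    melanoma_logits: np.ndarray, scores: np.ndarray, return_grad: bool = False
):
    """Pairwise ranking cross-entropy over all unordered pairs in a batch.

    For each pair i<j let o_ij = f_i - f_j (difference of melanoma logits),
    P_ij = sigmoid(o_ij), and P̄_ij the score-derived target.  The pair cost
    is the cross-entropy -P̄·log P - (1-P̄)·log(1-P), evaluated in the
    numerically stable form -P̄·o + log(1 + e^o); the loss is the mean over
    pairs.  A batch with fewer than two samples has no pairs: the loss is
    defined as 0 (with a warning) so ablation presets degrade gracefully.
    """
    f = np.asarray(melanoma_logits, dtype=np.float64).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if f.shape != s.shape:
        raise ValueError("melanoma_logits and scores must have equal length")
    n = f.size
    if n < 2:
        warnings.warn("ranking_loss on a batch of size < 2: no pairs, loss is 0")
        if return_grad:
            return 0.0, np.zeros_like(np.asarray(melanoma_logits, dtype=np.float64))
        return 0.0

    i_idx, j_idx = np.triu_indices(n, k=1)
    o = f[i_idx] - f[j_idx]
    pbar = np.where(s[i_idx] > s[j_idx], 1.0, np.where(s[i_idx] < s[j_idx], 0.0, 0.5))
    # log(1 + e^o) computed stably for both signs of o
    log1pexp = np.logaddexp(0.0, o)
    loss = float(np.mean(-pbar * o + log1pexp))
    if not return_grad:
        return loss
    # d/do of the pair cost is sigmoid(o) - P̄; scatter back onto f_i and f_j
    dpair = (_sigmoid(o) - pbar) / o.size
    grad = np.zeros(n, dtype=np.float64)
    np.add.at(grad, i_idx, dpair)
    np.add.at(grad, j_idx, -dpair)
    return loss, grad.reshape(np.asarray(melanoma_logits).shape)


def disease_supervised_loss(
    disease_logits: np.ndarray, labels: np.ndarray, return_grad: bool = False
):
    """Mean softmax cross-entropy on the two-way disease head."""
    z = np.asarray(disease_logits, dtype=np.float64)
    y = np.asarray(labels)
    if z.ndim != 2 or z.shape[0] != y.shape[0]:
        raise ValueError("disease_logits must be (batch, n_classes) aligned with labels")
    if np.any((y < 0) | (y >= z.shape[1])):
        raise ValueError("disease label out of range")
    zs = z - z.max(axis=1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    n = z.shape[0]
    loss = float(-logp[np.arange(n), y].mean())
    if not return_grad:
        return loss
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def feature_supervised_loss(
    feature_logits: np.ndarray,
    feature_labels: np.ndarray,
    feature_weights=(1.0, 1.0, 1.0),
    return_grad: bool = False,
):
    """Weighted mean sigmoid BCE over the three checklist-feature heads.

    The per-feature weights are normalized to sum to the feature count, so
    (1, 1, 1) reproduces the plain mean and (2, 1, 1) is the
    asymmetry-emphasis variant.
    """
    z = np.asarray(feature_logits, dtype=np.float64)
    y = np.asarray(feature_labels, dtype=np.float64)
    if z.shape != y.shape or z.ndim != 2:
        raise ValueError("feature_logits and feature_labels must be (batch, n_features)")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("feature labels must be binary")
    w = np.asarray(feature_weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("feature weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("feature weights must not all be zero")
    w = w * (w.size / w.sum())
    # BCE(z, y) = max(z,0) - z*y + log(1+e^{-|z|}), the stable elementwise form
    elem = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    per_feature = elem.mean(axis=0)
    loss = float((w * per_feature).mean())
    if not return_grad:
        return loss
    grad = (w / (z.shape[0] * w.size)) * (_sigmoid(z) - y)
    return loss, grad


def consistency_loss(
    student_disease_logits: np.ndarray,
    student_feature_logits: np.ndarray,
    teacher_disease_logits: np.ndarray,
    teacher_feature_logits: np.ndarray,
    heads: str = "both",
    return_grad: bool = False,
):
    """Mean-teacher consistency cost between student and teacher predictions.

    Each head's logits are mapped to predicted probabilities (softmax for
    disease, elementwise sigmoid for features) and the cost is the mean
    squared difference per head, summed over the enabled heads.  Teacher
    outputs are constants: no gradient is returned for them.

    ``heads`` selects ``"both"``, ``"disease"`` or ``"features"``.
    """
    if heads not in ("both", "disease", "features"):
        raise ValueError(f"unknown heads mode {heads!r}")
    zd = np.asarray(student_disease_logits, dtype=np.float64)
    zf = np.asarray(student_feature_logits, dtype=np.float64)
    td = np.asarray(teacher_disease_logits, dtype=np.float64)
    tf = np.asarray(teacher_feature_logits, dtype=np.float64)
    if zd.shape != td.shape or zf.shape != tf.shape:
        raise ValueError("student and teacher output shapes must match")

    loss = 0.0
    grad_d = np.zeros_like(zd)
    grad_f = np.zeros_like(zf)
    if heads in ("both", "disease"):
        p, q = _softmax(zd), _softmax(td)
        d = p - q
        loss += float((d**2).mean())
        if return_grad:
            # chain through the softmax: J^T v = p*(v - <v, p>)
            v = 2.0 * d / d.size
            grad_d = p * (v - (v * p).sum(axis=1, keepdims=True))
    if heads in ("both", "features"):
        p, q = _sigmoid(zf), _sigmoid(tf)
        d = p - q
        loss += float((d**2).mean())
        if return_grad:
            grad_f = (2.0 * d / d.size) * p * (1.0 - p)
    if return_grad:
        return loss, grad_d, grad_f
    return loss


def combined_loss(
    dsl: float | None,
    fsl: float | None,
    rl: float | None,
    cl: float | None,
    weights: LossWeights,
) -> float:
    """Weighted sum of the four loss terms.

    A term whose coefficient is zero is skipped entirely and may be passed
    as ``None`` — disabled losses never require their labels to have been
    computed.
    """
    parts = {
        "dsl": (weights.lambda_dsl, dsl),
        "fsl": (weights.lambda_fsl, fsl),
        "rl": (weights.lambda_rl, rl),
        "cl": (weights.lambda_cl, cl),
    }
    total = 0.0
    for name, (lam, value) in parts.items():
        if lam == 0:
            continue
        if value is None:
            raise ValueError(f"loss term {name!r} has weight {lam} but no value")
        if not np.isfinite(value):
            raise ValueError(f"loss term {name!r} is not finite: {value}")
        total += lam * value
    return total
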