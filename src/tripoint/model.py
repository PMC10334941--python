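"""Two-headed lesion classifier with a mean-teacher EMA copy.

One shared convolutional trunk ends in global average pooling; two linear
heads read the pooled representation: a 2-way softmax head for the disease
(melanoma vs melanocytic nevus) and a 3-way independent-sigmoid head for
the checklist features (asymmetry, atypical network, blue-white structure).
The melanoma logit of the disease head is ``f``, the quantity the ranking
loss orders.

The teacher is a structural copy of the student whose parameters are
updated only by exponential moving average, θ' ← α·θ' + (1−α)·θ — never by
gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    Param,
    ReLU,
    Residual,
    Sequential,
)

__all__ = ["ModelOutputs", "MultiHeadNet", "ModelState", "build_model", "ema_update",
           "save_checkpoint", "load_checkpoint", "BACKBONES"]

MELANOMA = 1  # index of the melanoma logit in the disease head


@dataclass
class ModelOutputs:
    """Logits from one forward pass of either branch."""

    disease_logits: np.ndarray  # (batch, 2): [nevus, melanoma]
    feature_logits: np.ndarray  # (batch, 3): [asymmetry, network, blue-white]

    @property
    def f(self) -> np.ndarray:
        """The melanoma logit — the ranking loss's input."""
        return self.disease_logits[:, MELANOMA]


class MultiHeadNet:
    """Shared trunk + pooled representation + disease/feature heads."""

    def __init__(self, trunk: Sequential, feat_dim: int, n_diseases: int,
                 n_features: int, rng: np.random.Generator, dtype=np.float32):
        self.trunk = trunk
        self.pool = GlobalAvgPool()
        self.head_disease = Linear(feat_dim, n_diseases, rng=rng, dtype=dtype)
        self.head_feature = Linear(feat_dim, n_features, rng=rng, dtype=dtype)

    def params(self) -> list[Param]:
        return (
            self.trunk.params()
            + self.head_disease.params()
            + self.head_feature.params()
        )

    def buffers(self) -> list[np.ndarray]:
        return self.trunk.buffers()

    def forward(self, x: np.ndarray, train: bool = False) -> ModelOutputs:
        h = self.trunk.forward(x, train)
        z = self.pool.forward(h, train)
        return ModelOutputs(
            disease_logits=self.head_disease.forward(z, train),
            feature_logits=self.head_feature.forward(z, train),
        )

    def backward(self, grad_disease: np.ndarray, grad_feature: np.ndarray) -> None:
        gz = self.head_disease.backward(grad_disease)
        gz = gz + self.head_feature.backward(grad_feature)
        self.trunk.backward(self.pool.backward(gz))


def _tiny_cnn(rng: np.random.Generator, dtype) -> tuple[Sequential, int]:
    """Four stride-2 conv/BN/ReLU blocks: 64×64×3 → 4×4×64."""
    chans = [3, 8, 16, 32, 64]
    layers = []
    for cin, cout in zip(chans[:-1], chans[1:]):
        layers += [
            Conv2d(cin, cout, kernel=3, stride=2, pad=1, rng=rng, dtype=dtype),
            BatchNorm2d(cout, dtype=dtype),
            ReLU(),
        ]
    return Sequential(*layers), chans[-1]


def _basic_block(cin: int, cout: int, stride: int, rng, dtype) -> Residual:
    body = Sequential(
        Conv2d(cin, cout, 3, stride, 1, rng=rng, dtype=dtype),
        BatchNorm2d(cout, dtype=dtype),
        ReLU(),
        Conv2d(cout, cout, 3, 1, 1, rng=rng, dtype=dtype),
        BatchNorm2d(cout, dtype=dtype),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = Sequential(
            Conv2d(cin, cout, 1, stride, 0, rng=rng, dtype=dtype),
            BatchNorm2d(cout, dtype=dtype),
        )
    return Residual(body, shortcut)


def _resnet18_style(rng: np.random.Generator, dtype) -> tuple[Sequential, int]:
    """A narrow ResNet-18-shaped trunk: stem + 4 stages of 2 basic blocks."""
    widths = [16, 16, 32, 64, 128]
    layers: list = [
        Conv2d(3, widths[0], 3, 1, 1, rng=rng, dtype=dtype),
        BatchNorm2d(widths[0], dtype=dtype),
        ReLU(),
    ]
    cin = widths[0]
    for stage, cout in enumerate(widths[1:]):
        stride = 1 if stage == 0 else 2
        layers += [_basic_block(cin, cout, stride, rng, dtype), ReLU()]
        layers += [_basic_block(cout, cout, 1, rng, dtype), ReLU()]
        cin = cout
    return Sequential(*layers), cin


BACKBONES = {"tiny_cnn": _tiny_cnn, "resnet18_style": _resnet18_style}


@dataclass
class ModelState:
    """Student, EMA teacher, and the bookkeeping tying them together."""

    student: MultiHeadNet
    teacher: MultiHeadNet
    ema_decay: float
    step: int = 0
    backbone: str = "tiny_cnn"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ValueError("ema_decay must lie in [0, 1]")


def _copy_into(dst: MultiHeadNet, src: MultiHeadNet) -> None:
    for pd, ps in zip(dst.params(), src.params()):
        pd.value[...] = ps.value
    for bd, bs in zip(dst.buffers(), src.buffers()):
        bd[...] = bs


def build_model(
    backbone: str = "tiny_cnn",
    n_diseases: int = 2,
    n_features: int = 3,
    seed: int = 0,
    ema_decay: float = 0.99,
    dtype=np.float32,
) -> ModelState:
    """Construct a student and an identical teacher copy.

    The same seed always yields the same initial parameters; the teacher
    starts as an exact copy of the student, so their forward passes agree
    until training diverges them.
    """
    if backbone not in BACKBONES:
        raise ValueError(
            f"unknown backbone {backbone!r}; supported: {sorted(BACKBONES)}"
        )

    def make() -> MultiHeadNet:
        rng = np.random.default_rng(seed)
        trunk, feat_dim = BACKBONES[backbone](rng, dtype)
        return MultiHeadNet(trunk, feat_dim, n_diseases, n_features, rng, dtype)

    student = make()
    teacher = make()  # same seed => identical structure and values
    _copy_into(teacher, student)
    return ModelState(student=student, teacher=teacher, ema_decay=ema_decay,
                      backbone=backbone)


def ema_update(state: ModelState, alpha: float | None = None) -> ModelState:
    """Teacher update θ' ← α·θ' + (1−α)·θ, elementwise over every parameter.

    Batch-norm running statistics are carried over from the student by the
    same rule so the teacher's evaluation-mode behaviour tracks the data it
    has seen.
    """
    a = state.ema_decay if alpha is None else alpha
    if not 0.0 <= a <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    sp, tp = state.student.params(), state.teacher.params()
    if len(sp) != len(tp) or any(p.value.shape != q.value.shape for p, q in zip(sp, tp)):
        raise ValueError("student/teacher parameter shapes do not match")
    for ps, pt in zip(sp, tp):
        pt.value *= a
        pt.value += ((1.0 - a) * ps.value).astype(pt.value.dtype, copy=False)
    for bs, bt in zip(state.student.buffers(), state.teacher.buffers()):
        bt *= a
        bt += ((1.0 - a) * bs).astype(bt.dtype, copy=False)
    return state


def save_checkpoint(state: ModelState, path, extra: dict | None = None) -> None:
    """Self-describing checkpoint: versioned npz of all arrays + a JSON header."""
    arrays = {}
    for prefix, net in (("student", state.student), ("teacher", state.teacher)):
        for i, p in enumerate(net.params()):
            arrays[f"{prefix}_p{i}"] = p.value
        for i, b in enumerate(net.buffers()):
            arrays[f"{prefix}_b{i}"] = b
    header = {
        "format": "tripoint-checkpoint",
        "version": 1,
        "backbone": state.backbone,
        "ema_decay": state.ema_decay,
        "step": state.step,
        "extra": extra or {},
    }
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format") != "tripoint-checkpoint":
            raise ValueError(f"{path} is not a tripoint checkpoint")
        state = build_model(backbone=header["backbone"], ema_decay=header["ema_decay"])
        state.step = header["step"]
        for prefix, net in (("student", state.student), ("teacher", state.teacher)):
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"{prefix}_p{i}"]
            for i, b in enumerate(net.buffers()):
                b[...] = data[f"{prefix}_b{i}"]
    return state
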