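"""Desk-scale mirror experiments.

The study-scale results (GPU training on archive dermoscopy) are out of
reach for a test suite, so these experiments reproduce the *structure* of
the evaluation on synthetic data at desk scale: the loss-ablation grid, the
ranking-loss comparison, and the few-label semisupervised comparison.  Each
function runs the full package pipeline end to end and returns plain
numbers; nothing here is precomputed.
"""

from __future__ import annotations

import numpy as np

from .evaluation import FEATURE_NAMES, evaluate_model
from .model import build_model, ema_update
from .preprocessing import PreprocessConfig
from .synthetic import SyntheticConfig, generate_dataset
from .training import (
    PRESETS,
    TrainConfig,
    train_semisupervised,
    train_supervised,
)
from .workbench import datasets_from_synthetic

__all__ = ["table_mirror", "gradient_check", "ema_decay_error"]

# synthetic renders are high-contrast already; CLAHE would flatten the
# constructed brightness cue, so mirror runs use crop + color constancy
_MIRROR_STAGES = ("crop_resize", "color_constancy")


def _mirror_data(seed: int):
    syn = SyntheticConfig(seed=seed)  # 900 labeled / 2000 unlabeled / 400 holdout
    pre = PreprocessConfig(target_size=syn.image_size, enabled_stages=_MIRROR_STAGES)
    return datasets_from_synthetic(generate_dataset(syn), pre)


def table_mirror(seed: int = 0, n_seeds: int = 5, sup_epochs: int = 45,
                 fsl_epochs: int = 25, semi_epochs: int = 10,
                 n_small_labeled: int = 90, verbose: bool = False) -> dict:
    """Loss-ablation mirror on the synthetic study design.

    Runs, on one generated dataset (720 train / 180 val labeled, 2000
    unlabeled, 400 holdout):

    * one feature-supervised (FSL) run — per-feature holdout AUC;
    * ``n_seeds`` disease-supervised (DSL) runs and DSL+ranking (DSL+RL)
      runs — holdout disease accuracy and the ranking-loss
      non-degradation comparison;
    * ``n_seeds`` paired few-label runs — DSL alone on ``n_small_labeled``
      images vs mean-teacher DSL+FSL+CL on the same images plus the
      unlabeled pool.

    Returns a flat dict of per-run metrics and summary counts.
    """
    labeled, unlabeled, val, holdout = _mirror_data(seed)

    def log(msg):
        if verbose:
            print(msg, flush=True)

    out: dict = {}

    cfg = TrainConfig(seed=seed, max_epochs=fsl_epochs,
                      loss_weights=PRESETS["FSL"])
    state, _ = train_supervised(labeled, cfg, val=val)
    rep = evaluate_model(state, holdout)
    out["fsl_feature_auc"] = {f: rep.per_head[f]["auc"] for f in FEATURE_NAMES}
    log(f"FSL feature AUC: {out['fsl_feature_auc']}")

    dsl_acc, dslrl_acc = [], []
    for k in range(n_seeds):
        run_seed = seed + 100 + k
        for name, store in (("DSL", dsl_acc), ("DSL+RL", dslrl_acc)):
            cfg = TrainConfig(seed=run_seed, max_epochs=sup_epochs,
                              loss_weights=PRESETS[name])
            state, _ = train_supervised(labeled, cfg, val=val)
            acc = evaluate_model(state, holdout).per_head["disease"]["accuracy"]
            store.append(acc)
            log(f"seed {run_seed} {name}: disease acc {acc:.3f}")
    out["dsl_disease_acc"] = dsl_acc
    out["dslrl_disease_acc"] = dslrl_acc
    out["rl_nondegradation_wins"] = int(
        sum(r >= d - 0.02 for d, r in zip(dsl_acc, dslrl_acc)))

    sup_small, semi_small = [], []
    for k in range(n_seeds):
        run_seed = seed + 200 + k
        rng = np.random.default_rng(run_seed)
        small = labeled.subset(rng.choice(len(labeled), n_small_labeled,
                                          replace=False))
        cfg = TrainConfig(seed=run_seed, max_epochs=sup_epochs,
                          loss_weights=PRESETS["DSL"])
        state, _ = train_supervised(small, cfg, val=val)
        sup_small.append(
            evaluate_model(state, holdout).per_head["disease"]["accuracy"])
        cfg = TrainConfig(seed=run_seed, max_epochs=semi_epochs,
                          loss_weights=PRESETS["DSL+FSL+CL"],
                          use_unlabeled_disease=False)
        state, _ = train_semisupervised(small, unlabeled, cfg, val=val)
        semi_small.append(
            evaluate_model(state, holdout).per_head["disease"]["accuracy"])
        log(f"seed {run_seed} few-label: sup {sup_small[-1]:.3f} "
            f"semi {semi_small[-1]:.3f}")
    out["supervised_90_acc"] = sup_small
    out["semisupervised_90_acc"] = semi_small
    out["semisup_wins"] = int(
        sum(s >= p for p, s in zip(sup_small, semi_small)))
    return out


def gradient_check(seed: int = 0, batch: int = 6, eps: float = 1e-5) -> float:
    """Max relative error of the combined-loss gradient on a small probe.

    A two-layer convolutional probe (float64, no normalization layers) is
    trained nowhere: the analytic backward pass of DSL + FSL + RL + CL is
    compared against central finite differences for every parameter.
    Returns the largest relative error over all parameters with
    non-negligible gradient.
    """
    from .losses import (
        consistency_loss,
        disease_supervised_loss,
        feature_supervised_loss,
        ranking_loss,
    )
    from .model import MELANOMA, MultiHeadNet
    from .nn import Conv2d, ReLU, Sequential

    rng = np.random.default_rng(seed)

    def probe():
        r = np.random.default_rng(seed + 1)
        trunk = Sequential(Conv2d(3, 4, 3, 2, 1, rng=r, dtype=np.float64), ReLU())
        return MultiHeadNet(trunk, 4, 2, 3, r, dtype=np.float64)

    net = probe()
    x = rng.random((batch, 3, 8, 8))
    y = rng.integers(0, 2, batch)
    feats = rng.integers(0, 2, (batch, 3)).astype(float)
    scores = feats.sum(axis=1)
    # fixed teacher outputs: the consistency target is a constant
    t_d = rng.normal(size=(batch, 2))
    t_f = rng.normal(size=(batch, 3))

    def loss_and_grads():
        out = net.forward(x, train=True)
        gd = np.zeros_like(out.disease_logits)
        gf = np.zeros_like(out.feature_logits)
        total = 0.0
        v, g = disease_supervised_loss(out.disease_logits, y, return_grad=True)
        total += v
        gd += g
        v, g = feature_supervised_loss(out.feature_logits, feats, return_grad=True)
        total += v
        gf += g
        v, g = ranking_loss(out.disease_logits[:, MELANOMA], scores,
                            return_grad=True)
        total += v
        gd[:, MELANOMA] += g
        v, g_d, g_f = consistency_loss(out.disease_logits, out.feature_logits,
                                       t_d, t_f, return_grad=True)
        total += v
        gd += g_d
        gf += g_f
        return total, gd, gf

    _, gd, gf = loss_and_grads()
    for p in net.params():
        p.grad[...] = 0.0
    net.backward(gd, gf)

    worst = 0.0
    for p in net.params():
        flat_v = p.value.ravel()
        flat_g = p.grad.ravel()
        for i in range(flat_v.size):
            orig = flat_v[i]
            flat_v[i] = orig + eps
            up, _, _ = loss_and_grads()
            flat_v[i] = orig - eps
            down, _, _ = loss_and_grads()
            flat_v[i] = orig
            numeric = (up - down) / (2 * eps)
            scale = max(abs(numeric), abs(flat_g[i]), 1e-8)
            worst = max(worst, abs(numeric - flat_g[i]) / scale)
    return worst


def ema_decay_error(alpha: float = 0.99, steps: int = 50, seed: int = 0) -> float:
    """Relative deviation of teacher-student distance from the α^t closed form."""
    state = build_model("tiny_cnn", seed=seed, dtype=np.float64)
    rng = np.random.default_rng(seed)
    for p in state.teacher.params():
        p.value += rng.normal(0, 0.1, size=p.value.shape)

    def dist():
        return np.sqrt(sum(((pt.value - ps.value) ** 2).sum()
                           for ps, pt in zip(state.student.params(),
                                             state.teacher.params())))

    d0 = dist()
    for _ in range(steps):
        ema_update(state, alpha=alpha)
    return abs(dist() - alpha**steps * d0) / (alpha**steps * d0)
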