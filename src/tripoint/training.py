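"""Supervised and mean-teacher semisupervised training.

One core loop serves both regimes.  Each step draws a batch — all labeled in
the supervised case, a labeled/unlabeled mix in the semisupervised case —
and assembles the enabled loss terms:

* DSL on every sample carrying a disease label,
* FSL and RL on the feature-annotated (labeled) portion,
* CL between the student's and the EMA teacher's predictions on the whole
  batch, with independent augmentation draws per branch and a linear ramp on
  its coefficient over the first fraction of training.

Analytic loss gradients are summed at the two heads' logits and
backpropagated once; the teacher is advanced by EMA after every optimizer
step.  Disabled terms are skipped entirely, so a run with the feature losses
off never touches feature labels (the dataset counts accesses to prove it).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .losses import (
    LossWeights,
    consistency_loss,
    disease_supervised_loss,
    feature_supervised_loss,
    ranking_loss,
)
from .model import MELANOMA, build_model, ema_update
from .nn import SGD

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "ArrayDataset",
    "ReduceLROnPlateau",
    "five_fold_cv",
    "cross_validate",
    "train_supervised",
    "train_semisupervised",
    "run_ablation",
    "PRESETS",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    The optimizer is SGD with momentum under a reduce-on-plateau schedule
    (mode min, factor 0.5, relative threshold 0.01, patience 7).  The
    printed study-scale batch size is 128; the desk-scale default here is
    64, which matches the small backbone and image size.
    """

    batch_size: int = 64
    labeled_fraction_per_batch: float = 0.5
    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_factor: float = 0.5
    lr_threshold: float = 0.01
    lr_patience: int = 7
    max_epochs: int = 40
    early_stop_patience: int = 15
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    ema_decay: float = 0.99
    backbone: str = "tiny_cnn"
    augment: bool = True
    consistency_ramp_fraction: float = 0.2
    consistency_heads: str = "both"
    ema_warmup: bool = True  # effective decay min(ema_decay, (t+1)/(t+10))
    ranking_source: str = "labeled"  # or "teacher": score unlabeled via the teacher
    use_unlabeled_disease: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if not 0.0 < self.labeled_fraction_per_batch <= 1.0:
            raise ValueError("labeled_fraction_per_batch must lie in (0, 1]")
        if self.optimizer != "sgd":
            raise ValueError("only the sgd optimizer is supported")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_patience < 0:
            raise ValueError("lr_patience must be nonnegative")
        if self.ranking_source not in ("labeled", "teacher"):
            raise ValueError("ranking_source must be 'labeled' or 'teacher'")


@dataclass(frozen=True)
class FoldAssignment:
    fold_index: int
    train_ids: tuple
    val_ids: tuple


class ArrayDataset:
    """In-memory image dataset with instrumented feature-label access.

    ``features`` is behind a counting property so tests can verify that
    runs with the feature losses disabled never read checklist labels.
    """

    def __init__(self, images: np.ndarray, disease: np.ndarray,
                 features: np.ndarray | None = None, ids: list | None = None):
        self.images = np.ascontiguousarray(images, dtype=np.float32)  # (N,3,H,W)
        self.disease = np.asarray(disease, dtype=np.int64)
        self._features = None if features is None else np.asarray(features, dtype=np.float64)
        self.ids = list(ids) if ids is not None else list(range(len(self.disease)))
        self.feature_reads = 0
        if self.images.shape[0] != self.disease.shape[0]:
            raise ValueError("images and disease labels must align")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def has_features(self) -> bool:
        return self._features is not None

    @property
    def features(self) -> np.ndarray:
        if self._features is None:
            raise ValueError("dataset carries no checklist feature labels")
        self.feature_reads += 1
        return self._features

    @classmethod
    def from_samples(cls, samples, with_features: bool = True) -> "ArrayDataset":
        images = np.stack([s.image.pixels.transpose(2, 0, 1) for s in samples])
        disease = np.array([s.disease for s in samples])
        feats = None
        if with_features:
            feats = np.stack([s.annotation.as_array() for s in samples])
        ids = [s.image.image_id for s in samples]
        return cls(images, disease, feats, ids)

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        feats = None if self._features is None else self._features[idx]
        return ArrayDataset(self.images[idx], self.disease[idx], feats,
                            [self.ids[i] for i in idx])


class ReduceLROnPlateau:
    """Halve the learning rate after `patience` epochs without improvement.

    Mode "min" with a relative threshold: epoch loss v improves on the best
    b when v < b·(1 − threshold).  After more than `patience` consecutive
    non-improving epochs the rate is multiplied by `factor`.
    """

    def __init__(self, optimizer: SGD, factor: float = 0.5,
                 threshold: float = 0.01, patience: int = 7):
        self.optimizer = optimizer
        self.factor, self.threshold, self.patience = factor, threshold, patience
        self.best = math.inf
        self.num_bad = 0

    def step(self, value: float) -> None:
        if value < self.best * (1.0 - self.threshold):
            self.best = value
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.optimizer.lr *= self.factor
                self.num_bad = 0


def five_fold_cv(ids, labels, seed: int = 0, n_folds: int = 5) -> list[FoldAssignment]:
    """Stratified rotation of the id list into `n_folds` train/val splits.

    The list is shuffled once with the seed and sliced into near-equal,
    disease-stratified subsets; each subset serves as validation in turn,
    so every id appears in exactly one fold's validation set.
    """
    ids = list(ids)
    y = np.asarray(labels)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} ids, got {len(ids)}")
    if len(ids) != len(y):
        raise ValueError("ids and labels must align")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(ids)), y)):
        folds.append(FoldAssignment(
            fold_index=k,
            train_ids=tuple(ids[i] for i in tr),
            val_ids=tuple(ids[i] for i in va),
        ))
    return folds


def _augment(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent horizontal/vertical flips per image (labels are invariant)."""
    out = images
    hflip = rng.random(images.shape[0]) < 0.5
    vflip = rng.random(images.shape[0]) < 0.5
    if hflip.any() or vflip.any():
        out = images.copy()
        out[hflip] = out[hflip, :, :, ::-1]
        out[vflip] = out[vflip, :, ::-1, :]
    return out


def _predict(net, images: np.ndarray, batch: int = 256):
    ds_logits, ft_logits = [], []
    for i in range(0, images.shape[0], batch):
        out = net.forward(images[i : i + batch], train=False)
        ds_logits.append(out.disease_logits)
        ft_logits.append(out.feature_logits)
    return np.concatenate(ds_logits), np.concatenate(ft_logits)


def _validation_loss(state, dataset, w: LossWeights, cfg) -> float:
    """Combined loss over the enabled terms on a held-out set (no CL ramp)."""
    zd, zf = _predict(state.student, dataset.images)
    total, any_term = 0.0, False
    if w.lambda_dsl > 0:
        total += w.lambda_dsl * disease_supervised_loss(zd, dataset.disease)
        any_term = True
    if w.lambda_fsl > 0:
        total += w.lambda_fsl * feature_supervised_loss(
            zf, dataset.features, w.feature_weights)
        any_term = True
    if w.lambda_rl > 0 and len(dataset) >= 2:
        scores = dataset.features.sum(axis=1)
        total += w.lambda_rl * ranking_loss(zd[:, MELANOMA], scores)
        any_term = True
    if not any_term:
        # CL-only preset: monitor student/teacher disagreement instead
        td, tf = _predict(state.teacher, dataset.images)
        total = w.lambda_cl * consistency_loss(zd, zf, td, tf, heads=cfg.consistency_heads)
    return float(total)


def _train_core(labeled: ArrayDataset, unlabeled: ArrayDataset | None,
                val: ArrayDataset | None, config: TrainConfig,
                epoch_hook=None):
    w = config.loss_weights
    use_dsl, use_fsl = w.lambda_dsl > 0, w.lambda_fsl > 0
    use_rl, use_cl = w.lambda_rl > 0, w.lambda_cl > 0

    if (use_fsl or use_rl) and not labeled.has_features:
        raise ValueError(
            "feature supervised / ranking loss enabled but the labeled dataset "
            "carries no checklist feature labels")
    if use_cl and (unlabeled is None or len(unlabeled) == 0):
        warnings.warn("consistency loss enabled with no unlabeled data; "
                      "training degenerates to the supervised regime")
    if not use_cl and config.labeled_fraction_per_batch >= 1.0:
        unlabeled = None  # pool would never contribute; keep rng streams clean

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    state = build_model(config.backbone, seed=config.seed, ema_decay=config.ema_decay)
    opt = SGD(state.student.params(), lr=config.learning_rate, momentum=config.momentum)
    sched = ReduceLROnPlateau(opt, config.lr_factor, config.lr_threshold,
                              config.lr_patience)

    n_lab = len(labeled)
    mixed = unlabeled is not None and len(unlabeled) > 0
    if mixed:
        b_lab = max(1, int(round(config.batch_size * config.labeled_fraction_per_batch)))
        b_unl = max(1, config.batch_size - b_lab)
        steps_per_epoch = max(math.ceil(n_lab / b_lab), math.ceil(len(unlabeled) / b_unl))
    else:
        b_lab, b_unl = min(config.batch_size, n_lab), 0
        steps_per_epoch = math.ceil(n_lab / b_lab)
    total_steps = steps_per_epoch * config.max_epochs
    ramp_steps = max(1, int(config.consistency_ramp_fraction * total_steps))

    history: list[dict] = []
    best_val, bad_epochs = math.inf, 0
    for epoch in range(config.max_epochs):
        lab_order = rng.permutation(n_lab)
        unl_order = rng.permutation(len(unlabeled)) if mixed else None
        comp_sums = {"dsl": 0.0, "fsl": 0.0, "rl": 0.0, "cl": 0.0}
        correct, seen = 0, 0
        for step in range(steps_per_epoch):
            li = lab_order[(step * b_lab + np.arange(b_lab)) % n_lab]
            xl = labeled.images[li]
            if mixed:
                ui = unl_order[(step * b_unl + np.arange(b_unl)) % len(unlabeled)]
                xu = unlabeled.images[ui]
                x = np.concatenate([xl, xu])
            else:
                ui = None
                x = xl
            nb = x.shape[0]

            x_student = _augment(x, rng) if config.augment else x
            out = state.student.forward(x_student, train=True)
            gd = np.zeros_like(out.disease_logits, dtype=np.float64)
            gf = np.zeros_like(out.feature_logits, dtype=np.float64)

            if use_dsl:
                if mixed and config.use_unlabeled_disease:
                    y = np.concatenate([labeled.disease[li], unlabeled.disease[ui]])
                    sl = slice(0, nb)
                else:
                    y = labeled.disease[li]
                    sl = slice(0, b_lab)
                v, g = disease_supervised_loss(out.disease_logits[sl], y,
                                               return_grad=True)
                gd[sl] += w.lambda_dsl * g
                comp_sums["dsl"] += v
                correct += int((out.disease_logits[sl].argmax(axis=1) == y).sum())
                seen += y.size
            if use_fsl:
                feats = labeled.features[li]
                v, g = feature_supervised_loss(out.feature_logits[:b_lab], feats,
                                               w.feature_weights, return_grad=True)
                gf[:b_lab] += w.lambda_fsl * g
                comp_sums["fsl"] += v
            if use_rl:
                scores = labeled.features[li].sum(axis=1)
                f_logits = out.disease_logits[:b_lab, MELANOMA]
                sl_rl = slice(0, b_lab)
                if mixed and config.ranking_source == "teacher":
                    # score unlabeled samples with hard-thresholded teacher features
                    t_out = state.teacher.forward(x[b_lab:], train=False)
                    pseudo = (t_out.feature_logits > 0).sum(axis=1).astype(np.float64)
                    scores = np.concatenate([scores, pseudo])
                    f_logits = out.disease_logits[:, MELANOMA]
                    sl_rl = slice(0, nb)
                if f_logits.size >= 2:
                    v, g = ranking_loss(f_logits, scores, return_grad=True)
                    gd[sl_rl, MELANOMA] += w.lambda_rl * g
                    comp_sums["rl"] += v
            if use_cl:
                x_teacher = _augment(x, rng) if config.augment else x
                t_out = state.teacher.forward(x_teacher, train=False)
                lam_cl = w.lambda_cl * min(1.0, (state.step + 1) / ramp_steps)
                v, g_d, g_f = consistency_loss(
                    out.disease_logits, out.feature_logits,
                    t_out.disease_logits, t_out.feature_logits,
                    heads=config.consistency_heads, return_grad=True)
                gd += lam_cl * g_d
                gf += lam_cl * g_f
                comp_sums["cl"] += v

            opt.zero_grad()
            state.student.backward(gd.astype(np.float32), gf.astype(np.float32))
            opt.step()
            # early steps track the student closely so the freshly initialized
            # teacher is not an anchor to random weights
            alpha = min(config.ema_decay, (state.step + 1) / (state.step + 10)) \
                if config.ema_warmup else config.ema_decay
            ema_update(state, alpha)
            state.step += 1

        record = {
            "epoch": epoch,
            "lr": opt.lr,
            **{k: v / steps_per_epoch for k, v in comp_sums.items()},
            "train_accuracy": correct / seen if seen else math.nan,
        }
        if val is not None and len(val):
            val_loss = _validation_loss(state, val, w, config)
            zd, _ = _predict(state.student, val.images)
            record["val_loss"] = val_loss
            record["val_accuracy"] = float(
                (zd.argmax(axis=1) == val.disease).mean())
            sched.step(val_loss)
            if val_loss < best_val * (1.0 - 1e-12):
                best_val, bad_epochs = val_loss, 0
            else:
                bad_epochs += 1
        history.append(record)
        if epoch_hook is not None:
            epoch_hook(state, record)
        if val is not None and bad_epochs > config.early_stop_patience:
            break
    return state, history


def train_supervised(dataset: ArrayDataset, config: TrainConfig,
                     val: ArrayDataset | None = None, epoch_hook=None):
    """Train on feature/disease-annotated data with the supervised terms only.

    The consistency coefficient is ignored (there is no unlabeled pool);
    enabling FSL or RL on a dataset without feature labels is rejected at
    startup.
    """
    w = config.loss_weights
    if w.lambda_cl > 0:
        config = replace(config, loss_weights=replace(w, lambda_cl=0.0))
    return _train_core(dataset, None, val, config, epoch_hook=epoch_hook)


def train_semisupervised(labeled: ArrayDataset, unlabeled: ArrayDataset | None,
                         config: TrainConfig, val: ArrayDataset | None = None,
                         epoch_hook=None):
    """Mean-teacher training on a labeled pool plus an unlabeled pool.

    Each step draws a mixed batch; supervised terms see the labeled portion
    (DSL also sees unlabeled disease tags when present and enabled) and the
    consistency term compares student and teacher over the whole batch.
    """
    return _train_core(labeled, unlabeled, val, config, epoch_hook=epoch_hook)


def cross_validate(dataset: ArrayDataset, config: TrainConfig,
                   n_folds: int = 5):
    """Rotate stratified folds and report disease accuracy mean and SD.

    Each fold trains a fresh model on the other folds' samples and scores
    the held-out fold; the return value is (per-fold accuracies,
    (mean, sample SD)), the study protocol's summary of a configuration.
    """
    from .evaluation import evaluate_model, fold_aggregate

    idx = list(range(len(dataset)))
    folds = five_fold_cv(idx, dataset.disease, seed=config.seed,
                         n_folds=n_folds)
    accs = []
    for f in folds:
        tr = dataset.subset(list(f.train_ids))
        va = dataset.subset(list(f.val_ids))
        state, _ = _train_core(tr, None, va, config)
        rep = evaluate_model(state, va)
        accs.append(rep.per_head["disease"]["accuracy"])
    return accs, fold_aggregate(accs)


# The loss-combination grid: the study's ablation rows plus the
# human-knowledge (ranking) variants.
PRESETS: dict[str, LossWeights] = {
    "CL": LossWeights(0, 0, 0, 1),
    "DSL": LossWeights(1, 0, 0, 0),
    "FSL": LossWeights(0, 1, 0, 0),
    "FSL+CL": LossWeights(0, 1, 0, 1),
    "DSL+FSL": LossWeights(1, 1, 0, 0),
    "DSL+CL": LossWeights(1, 0, 0, 1),
    "DSL+FSL+CL": LossWeights(1, 1, 0, 1),
    "DSL+FSL(asym)+CL": LossWeights(1, 1, 0, 1, feature_weights=(2.0, 1.0, 1.0)),
    "DSL+RL": LossWeights(1, 0, 1, 0),
    "DSL+FSL+RL+CL": LossWeights(1, 1, 1, 1),
}


def run_ablation(presets, labeled: ArrayDataset, unlabeled: ArrayDataset | None,
                 holdout: ArrayDataset, config: TrainConfig):
    """Train one model per loss preset and report per-head metrics.

    ``presets`` maps row names to :class:`LossWeights` (or names in
    :data:`PRESETS`).  All rows share the seed and data; the result is a
    DataFrame shaped like the study's ablation table (rows = presets,
    columns = accuracy and AUC per head), each row stamped with the config
    hash that produced it.
    """
    import pandas as pd

    from .config import config_hash
    from .evaluation import evaluate_model

    if isinstance(presets, (list, tuple)):
        names = list(presets)
        if len(set(names)) != len(names):
            raise ValueError("duplicate preset names")
        presets = {n: PRESETS[n] for n in names}
    elif len(set(presets)) != len(presets):  # pragma: no cover - dict keys unique
        raise ValueError("duplicate preset names")

    rows = []
    for name, weights in presets.items():
        run_cfg = replace(config, loss_weights=weights)
        state, history = train_semisupervised(labeled, unlabeled, run_cfg)
        report = evaluate_model(state, holdout)
        row = {"preset": name}
        for head, metrics in report.per_head.items():
            row[f"{head}_accuracy"] = metrics["accuracy"]
            row[f"{head}_auc"] = metrics["auc"]
        row["epochs_run"] = len(history)
        row["config_hash"] = config_hash(run_cfg)
        rows.append(row)
    return pd.DataFrame(rows)
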