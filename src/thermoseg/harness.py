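"""Training loop, five-fold cross-validation, metrics, and reports.

The pipeline is trained in two phases.  Phase one optimizes the segmenter
and capsule extractor jointly with ADAM on the combined objective
``L_total = alpha * L_seg + beta * L_cls`` (soft Dice on the predicted mask
plus categorical cross-entropy on a capsule-side softmax head), with early
stopping on a held-out validation split.  Phase two freezes the network and
fits the extreme-learning-machine classifier in closed form on the frozen
capsule features of the training subjects.

Cross-validation is stratified at subject level: each subject (and any
augmented copies of it) lands in exactly one test fold, preserving the
cohort's diabetic/control proportions per fold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .caps import CapsConfig, CapsuleExtractor
from .elm import ElmModel, elm_fit, elm_init, elm_predict
from .nn import Tensor
from .preprocess import AugmentSpec, augment, enhance_histogram, screen_pixels
from .synthio import ThermogramRecord
from .umst import Umst, UmstConfig, dice_loss

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "MetricsReport",
    "PipelineModel",
    "make_folds",
    "combined_loss",
    "cross_entropy",
    "train",
    "evaluate",
    "segmentation_metrics",
    "classification_metrics",
    "dropout_sweep",
    "run_cv",
]

log = logging.getLogger("thermoseg")

METRIC_COLUMNS = ["dsc", "iou", "seg_precision", "seg_recall",
                  "accuracy", "precision", "recall", "f1"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The defaults mirror the training protocol this package implements:
    initial learning rate 0.001, up to 289 epochs, batch size 30, ADAM.
    ``momentum_param`` is recorded for provenance; ADAM ignores it (it is
    used only when ``optimizer='sgd'``).
    """

    lr: float = 0.001
    epochs_max: int = 289
    batch_size: int = 30
    optimizer: str = "adam"
    momentum_param: float = 0.02
    early_stop_patience: int = 20
    min_delta: float = 1e-4
    alpha: float = 0.6
    beta: float = 0.4
    dropout: float = 0.0
    val_fraction: float = 0.1
    grad_clip: float = 1.0   # global gradient-norm ceiling; 0 disables
    lr_schedule: str = "constant"  # or "cosine" decay from lr
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError(f"lr must be > 0, got {self.lr}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")


@dataclass
class FoldPlan:
    """Subject-level fold assignment for k-fold cross-validation."""

    k: int
    fold_of: dict[str, int]                      # subject_code -> fold index
    folds: list[tuple[list[str], list[str]]]     # (train_codes, test_codes)

    def test_subjects(self, fold: int) -> list[str]:
        return self.folds[fold][1]

    def train_subjects(self, fold: int) -> list[str]:
        return self.folds[fold][0]


def make_folds(records: list[ThermogramRecord], k: int = 5,
               seed: int = 0) -> FoldPlan:
    """Stratified subject-level partition into k folds, deterministic per seed."""
    label_of: dict[str, int] = {}
    for rec in records:
        code = rec.meta.subject_code
        if code in label_of and label_of[code] != rec.label:
            raise ValueError(f"subject {code} appears with conflicting labels")
        label_of[code] = rec.label
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for label in sorted(set(label_of.values())):
        codes = sorted(c for c, lab in label_of.items() if lab == label)
        if len(codes) < k:
            raise ValueError(
                f"class {label} has {len(codes)} subjects; at least {k} "
                f"are required for {k}-fold cross-validation")
        rng.shuffle(codes)
        for i, code in enumerate(codes):
            fold_of[code] = i % k
    folds = []
    all_codes = sorted(label_of)
    for f in range(k):
        test = [c for c in all_codes if fold_of[c] == f]
        trainc = [c for c in all_codes if fold_of[c] != f]
        folds.append((trainc, test))
    return FoldPlan(k=k, fold_of=fold_of, folds=folds)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cross_entropy(cls_logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits (log-softmax inside)."""
    onehot = np.atleast_2d(np.asarray(onehot, dtype=np.float64))
    shifted = cls_logits - Tensor(cls_logits.data.max(axis=-1, keepdims=True))
    log_z = shifted.exp().sum(axis=-1, keepdims=True).log()
    log_probs = shifted - log_z
    n = onehot.shape[0]
    return -(log_probs * Tensor(onehot)).sum() / n


def combined_loss(seg_logits: Tensor, mask, cls_logits: Tensor, onehot,
                  alpha: float = 0.6, beta: float = 0.4,
                  dice_eps: float = 1.0) -> Tensor:
    """alpha * Dice loss + beta * categorical cross-entropy."""
    loss = alpha * dice_loss(seg_logits, mask, eps=dice_eps)
    if beta != 0.0:
        loss = loss + beta * cross_entropy(cls_logits, onehot)
    return loss


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def segmentation_metrics(S, T) -> tuple[float, float, float, float]:
    """(DSC, IoU, precision, recall) between predicted mask S and truth T.

    DSC = 2|S n T| / (|S| + |T|); IoU = |S n T| / |S u T|;
    precision = |S n T| / |S|; recall = |S n T| / |T|.
    An empty union counts as perfect agreement (all four = 1).
    """
    S = np.asarray(S).astype(bool)
    T = np.asarray(T).astype(bool)
    if S.shape != T.shape:
        raise ValueError(f"mask shapes differ: {S.shape} vs {T.shape}")
    inter = np.logical_and(S, T).sum()
    s, t = int(S.sum()), int(T.sum())
    union = s + t - inter
    if union == 0:
        return 1.0, 1.0, 1.0, 1.0
    dsc = 2.0 * inter / (s + t)
    iou = inter / union
    precision = inter / s if s else 0.0
    recall = inter / t if t else 0.0
    return float(dsc), float(iou), float(precision), float(recall)


def classification_metrics(pred_labels, true_labels) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) with the diabetic class (1) positive."""
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.size == 0:
        raise ValueError("empty label vectors")
    if pred.shape != true.shape:
        raise ValueError(f"label vectors differ in length: {pred.shape} vs {true.shape}")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    accuracy = (tp + tn) / pred.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return float(accuracy), float(precision), float(recall), float(f1)


@dataclass
class MetricsReport:
    """Per-fold metric table with mean and standard-deviation rows."""

    table: pd.DataFrame

    @classmethod
    def from_folds(cls, fold_rows: list[dict]) -> "MetricsReport":
        df = pd.DataFrame(fold_rows, columns=METRIC_COLUMNS)
        df.index = [f"fold{i}" for i in range(len(fold_rows))]
        df.loc["mean"] = df.iloc[:len(fold_rows)].mean()
        df.loc["sd"] = df.iloc[:len(fold_rows)].std(ddof=0)
        return cls(table=df)

    @property
    def mean(self) -> pd.Series:
        return self.table.loc["mean"]

    def to_csv(self, path):
        self.table.to_csv(path, index_label="fold")


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Sizes and constants for the full segment-extract-classify pipeline."""

    image_size: int = 64
    umst: UmstConfig = field(default_factory=UmstConfig)
    caps: CapsConfig = field(default_factory=CapsConfig)
    n_classes: int = 2
    elm_hidden: int = 64
    elm_C: float = 1e3


class PipelineModel(nn.Module):
    """U-MST segmenter + capsule extractor + softmax training head + ELM."""

    def __init__(self, cfg: PipelineConfig, seed: int):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.seed = seed
        self.umst = Umst(cfg.umst, rng, image_size=cfg.image_size)
        self._bottleneck_grid = cfg.image_size // cfg.umst.patch_size // 4
        caps_in = cfg.umst.stage_dims[-1] + (1 if cfg.caps.use_mask_channel else 0)
        self.caps = CapsuleExtractor(caps_in, self._bottleneck_grid,
                                     cfg.caps, rng)
        self.cls_head = nn.Linear(cfg.caps.feature_len, cfg.n_classes, rng)
        self.elm: ElmModel | None = None

    def forward(self, images) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (segmentation logits, capsule features Z, class logits)."""
        seg_logits = self.umst(images)
        feats = self.umst.bottleneck_features()
        if self.cfg.caps.use_mask_channel:
            # pooled predicted-lesion probability as an extra capsule input
            probs = nn.softmax(seg_logits, axis=-1)[..., 1]
            b, h, w = probs.shape
            g = self._bottleneck_grid
            f = h // g
            pooled = probs.reshape(b, g, f, g, f).mean(axis=(2, 4))
            feats = nn.concatenate([feats, pooled.reshape(b, g, g, 1)], axis=-1)
        Z = self.caps(feats)
        return seg_logits, Z, self.cls_head(Z)

    def features(self, images) -> np.ndarray:
        """Frozen capsule features for a batch (eval mode, no grads)."""
        was = self.training
        self.eval()
        try:
            _, Z, _ = self.forward(images)
        finally:
            self.train(was)
        return Z.numpy()

    def predict_labels(self, images) -> np.ndarray:
        """ELM class predictions; requires a fitted ELM head."""
        if self.elm is None:
            raise RuntimeError("ELM head not fitted; run train() first")
        probs = elm_predict(self.elm, self.features(images))
        return probs.argmax(axis=1)


def _set_dropout(model: PipelineModel, rate: float):
    for mod in model.modules():
        if isinstance(mod, nn.Dropout):
            mod.rate = rate


def _stack_images(records: list[ThermogramRecord]) -> np.ndarray:
    return np.stack([r.image for r in records])


def _stack_masks(records: list[ThermogramRecord]) -> np.ndarray:
    return np.stack([r.mask if r.mask is not None
                     else np.zeros_like(r.image, dtype=np.uint8)
                     for r in records])


def _onehot(labels, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_loss(model: PipelineModel, batch: list[ThermogramRecord],
                cfg: TrainConfig) -> Tensor:
    images = _stack_images(batch)
    masks = _stack_masks(batch)
    onehot = _onehot([r.label for r in batch], model.cfg.n_classes)
    seg_logits, _, cls_logits = model(images)
    return combined_loss(seg_logits, masks, cls_logits, onehot,
                         alpha=cfg.alpha, beta=cfg.beta)


def train(model: PipelineModel, train_records: list[ThermogramRecord],
          val_records: list[ThermogramRecord] | None, cfg: TrainConfig,
          fit_elm: bool = True) -> dict:
    """Two-phase training; returns a history dict.

    Phase one: ADAM (or SGD) on the combined loss with early stopping on the
    validation loss (best weights are restored).  Phase two: closed-form ELM
    fit on frozen capsule features of the training records.
    """
    rng = np.random.default_rng(cfg.seed)
    _set_dropout(model, cfg.dropout)
    params = list(model.parameters())
    if cfg.optimizer == "adam":
        opt = nn.Adam(params, lr=cfg.lr)
    else:
        opt = nn.SGD(params, lr=cfg.lr, momentum=cfg.momentum_param)

    history = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
    best_val = np.inf
    best_state = model.state_dict()
    patience_left = cfg.early_stop_patience
    n = len(train_records)

    for epoch in range(cfg.epochs_max):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs_max))
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            batch = [train_records[i] for i in order[lo:lo + cfg.batch_size]]
            model.zero_grad()
            loss = _batch_loss(model, batch, cfg)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={cfg.lr}); aborting")
            loss.backward()
            if cfg.grad_clip > 0:
                total = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params
                                    if p.grad is not None))
                if total > cfg.grad_clip:
                    scale = cfg.grad_clip / total
                    for p in params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))

        monitor = history["train_loss"][-1]
        if val_records:
            model.eval()
            monitor = _batch_loss(model, val_records, cfg).item()
        history["val_loss"].append(float(monitor))
        if monitor < best_val - cfg.min_delta:
            best_val = monitor
            best_state = model.state_dict()
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left < 0:
                history["stopped_epoch"] = epoch
                break

    model.load_state_dict(best_state)
    model.eval()
    if fit_elm:
        Z = model.features(_stack_images(train_records))
        onehot = _onehot([r.label for r in train_records], model.cfg.n_classes)
        elm = elm_init(model.cfg.caps.feature_len, model.cfg.elm_hidden,
                       seed=cfg.seed)
        model.elm, report = elm_fit(elm, Z, onehot, C=model.cfg.elm_C)
        history["elm_train_error"] = report.train_error
    return history


def evaluate(model: PipelineModel,
             records: list[ThermogramRecord]) -> dict[str, float]:
    """Mean segmentation metrics and ELM classification metrics on records."""
    seg_out = model.umst.segment(_stack_images(records))
    seg_vals = []
    for i, rec in enumerate(records):
        if rec.mask is not None:
            seg_vals.append(segmentation_metrics(seg_out.mask[i], rec.mask))
    seg_mean = (np.mean(seg_vals, axis=0) if seg_vals
                else np.array([np.nan] * 4))
    pred = model.predict_labels(_stack_images(records))
    true = [r.label for r in records]
    acc, prec, rec_, f1 = classification_metrics(pred, true)
    return dict(zip(METRIC_COLUMNS,
                    [*map(float, seg_mean), acc, prec, rec_, f1]))


# ---------------------------------------------------------------------------
# cross-validation and sweeps
# ---------------------------------------------------------------------------

def _preprocess_records(records: list[ThermogramRecord], screen: bool,
                        enhance: bool) -> list[ThermogramRecord]:
    if not (screen or enhance):
        return records
    out = []
    for rec in records:
        img = rec.image
        if screen:
            img = screen_pixels(img)
        if enhance:
            img = enhance_histogram(img)
        out.append(ThermogramRecord(meta=rec.meta, image=img, mask=rec.mask,
                                    label=rec.label))
    return out


def _split_validation(train_recs: list[ThermogramRecord], fraction: float,
                      seed: int) -> tuple[list[ThermogramRecord], list[ThermogramRecord]]:
    """Hold out a fraction of training subjects (at least one) for early stopping."""
    codes = sorted({r.meta.subject_code for r in train_recs})
    rng = np.random.default_rng(seed)
    rng.shuffle(codes)
    n_val = max(1, int(round(fraction * len(codes))))
    val_codes = set(codes[:n_val])
    tr = [r for r in train_recs if r.meta.subject_code not in val_codes]
    va = [r for r in train_recs if r.meta.subject_code in val_codes]
    return tr, va


def run_cv(records: list[ThermogramRecord], pipe_cfg: PipelineConfig,
           train_cfg: TrainConfig, k: int = 5,
           augment_spec: AugmentSpec | None = None,
           screen: bool = True, enhance: bool = False,
           out_dir=None) -> tuple[MetricsReport, FoldPlan]:
    """Subject-stratified k-fold cross-validation of the full pipeline.

    Augmentation, when requested, is applied to training folds only, after
    the split, so augmented copies always follow their source subject.
    Returns the metric report (per-fold rows plus mean and sd) and the fold
    plan; optionally writes ``metrics.csv`` and a run log to ``out_dir``.
    """
    records = _preprocess_records(records, screen, enhance)
    plan = make_folds(records, k=k, seed=train_cfg.seed)
    cfg_hash = hashlib.sha256(
        json.dumps([asdict(train_cfg), asdict(pipe_cfg.umst), asdict(pipe_cfg.caps)],
                   sort_keys=True, default=str).encode()).hexdigest()[:12]
    log.info("run_cv: %d records, k=%d, seed=%d, config-hash=%s",
             len(records), k, train_cfg.seed, cfg_hash)
    fold_rows = []
    fold_models: list[PipelineModel] = []
    for f in range(k):
        test_codes = set(plan.test_subjects(f))
        train_recs = [r for r in records if r.meta.subject_code not in test_codes]
        test_recs = [r for r in records if r.meta.subject_code in test_codes]
        tr, va = _split_validation(train_recs, train_cfg.val_fraction,
                                   seed=train_cfg.seed + 1000 + f)
        if augment_spec is not None and augment_spec.copies_per_image > 0:
            extra = []
            for rec in tr:
                extra.extend(augment(rec, augment_spec))
            tr = tr + extra
        model = PipelineModel(pipe_cfg, seed=train_cfg.seed + f)
        try:
            train(model, tr, va, train_cfg)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f}: {exc}") from exc
        row = evaluate(model, test_recs)
        log.info("fold %d: %s", f,
                 " ".join(f"{k_}={v:.3f}" for k_, v in row.items()))
        fold_rows.append(row)
        fold_models.append(model)
    report = MetricsReport.from_folds(fold_rows)
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "metrics.csv")
        with open(out / "run.log", "w") as fh:
            fh.write(f"seed={train_cfg.seed} k={k} config_hash={cfg_hash}\n")
            fh.write(report.table.to_string())
            fh.write("\n")
    report.models = fold_models  # kept for downstream inspection
    return report, plan


def dropout_sweep(records: list[ThermogramRecord], pipe_cfg: PipelineConfig,
                  train_cfg: TrainConfig, rates: list[float],
                  fold: int = 0, k: int = 5) -> pd.DataFrame:
    """Retrain one fold at each dropout rate; returns accuracy per rate."""
    for r in rates:
        if not 0.0 <= r <= 0.9:
            raise ValueError(f"dropout rates must lie in [0, 0.9], got {r}")
    plan = make_folds(records, k=k, seed=train_cfg.seed)
    test_codes = set(plan.test_subjects(fold))
    train_recs = [r for r in records if r.meta.subject_code not in test_codes]
    test_recs = [r for r in records if r.meta.subject_code in test_codes]
    tr, va = _split_validation(train_recs, train_cfg.val_fraction,
                               seed=train_cfg.seed + 1000 + fold)
    rows = []
    for rate in rates:
        cfg = replace(train_cfg, dropout=rate)
        model = PipelineModel(pipe_cfg, seed=train_cfg.seed + fold)
        train(model, tr, va, cfg)
        row = evaluate(model, test_recs)
        rows.append({"dropout": rate, "accuracy": row["accuracy"],
                     "f1": row["f1"], "dsc": row["dsc"]})
    return pd.DataFrame(rows)
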