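"""Stratified cross-validation training, ablations and baseline models.

All per-fold preprocessing statistics (imputation means/modes, standardizer)
are fitted strictly inside the training split of the fold — validation labels
or values can never leak into them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .config import ModelConfig, TrainConfig
from .encoders import EncodedBatch, StructuredTokenizer
from .fusion import FusionModel, masked_mean
from .metrics import MetricsReport
from .nn import Adam, Tensor, no_grad
from .objectives import (
    DivergenceError,
    ProjectionHead,
    Temperature,
    contrastive_loss,
    cross_entropy,
    l2_regularization,
    total_loss,
)
from .schema import Cohort, FieldStatistics, Standardizer, impute_record

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = ("full", "no_contrastive", "no_cross_attention",
                     "direct_fusion_gbt", "direct_fusion_fft")
SINGLE_MODALITY_VARIANTS = ("csv_only", "text_only")


@dataclass(frozen=True)
class FoldPlan:
    folds: list  # list of (train_indices, val_indices) int arrays
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def validate(self, labels: np.ndarray) -> None:
        n = len(labels)
        all_val = np.concatenate([v for _, v in self.folds])
        if sorted(all_val.tolist()) != list(range(n)):
            raise ValueError("validation folds must partition the cohort")
        global_pos = labels.sum() / n
        for train, val in self.folds:
            if set(train) & set(val):
                raise ValueError("train/val overlap")
            expected = global_pos * len(val)
            if abs(labels[val].sum() - expected) > 1 + 1e-9:
                raise ValueError("fold label proportion off by more than one count")


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded stratified K-fold plan over a label vector."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError("each class needs at least k members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]
    plan = FoldPlan(folds=folds, seed=seed)
    plan.validate(labels)
    return plan


# ---------------------------------------------------------------------------
# per-fold preprocessing (leakage-free)
# ---------------------------------------------------------------------------


@dataclass
class FoldPreprocessor:
    stats: FieldStatistics
    standardizer: Standardizer

    @staticmethod
    def fit(cohort: Cohort, train_idx: np.ndarray) -> "FoldPreprocessor":
        train_records = [cohort.records[i] for i in train_idx]
        stats = FieldStatistics.fit(train_records, cohort.schema)
        imputed = [impute_record(r, stats, cohort.schema) for r in train_records]
        standardizer = Standardizer.fit(imputed, cohort.schema)
        return FoldPreprocessor(stats=stats, standardizer=standardizer)

    def encode(self, cohort: Cohort, idx: np.ndarray, model: FusionModel) -> EncodedBatch:
        records = [impute_record(cohort.records[i], self.stats, cohort.schema)
                   for i in idx]
        st = StructuredTokenizer(cohort.schema)
        return st.encode_batch(records, self.standardizer, model.tokenizer)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _class_weights(labels: np.ndarray) -> np.ndarray:
    counts = np.bincount(labels, minlength=2).astype(float)
    counts = np.maximum(counts, 1.0)
    return len(labels) / (2.0 * counts)


def _build_model(schema, model_cfg: ModelConfig, seed: int) -> FusionModel:
    return FusionModel(
        cardinalities=schema.cardinalities,
        n_numeric=len(schema.numeric_fields),
        dim=model_cfg.dim,
        n_blocks=model_cfg.n_blocks,
        n_heads=model_cfg.n_heads,
        ffn_mult=model_cfg.ffn_mult,
        d_text=model_cfg.d_text,
        backbone_layers=model_cfg.backbone_layers,
        backbone_heads=model_cfg.backbone_heads,
        vocab_size=model_cfg.vocab_size,
        max_len=model_cfg.max_len,
        bidirectional=model_cfg.bidirectional,
        lambda_init=model_cfg.lambda_init,
        backbone_trainable=model_cfg.backbone_trainable,
        seed=seed,
    )


class TrainedFold:
    def __init__(self, model: FusionModel, head: ProjectionHead, temp: Temperature,
                 curves: pd.DataFrame):
        self.model = model
        self.head = head
        self.temp = temp
        self.curves = curves

    def predict(self, batch: EncodedBatch, threshold: float = 0.5,
                use_gca: bool = True) -> np.ndarray:
        with no_grad():
            probs = []
            for lo in range(0, len(batch), 256):
                sub = batch.subset(np.arange(lo, min(lo + 256, len(batch))))
                logits, _, _ = self.model(sub, use_gca=use_gca)
                probs.append(Tensor(logits.data).softmax(axis=-1).data[:, 1])
        return (np.concatenate(probs) > threshold).astype(int)


def train_fold(train_batch: EncodedBatch, val_batch: EncodedBatch,
               model: FusionModel, model_cfg: ModelConfig, train_cfg: TrainConfig,
               variant: str = "full") -> TrainedFold:
    """Train one fold with early stopping on validation total loss."""
    use_gca = variant != "no_cross_attention"
    beta = 0.0 if variant == "no_contrastive" else train_cfg.beta

    rng = np.random.default_rng(train_cfg.seed + 104729)
    head = ProjectionHead(model_cfg.dim, model_cfg.d_z, rng)
    temp = Temperature(model_cfg.tau_init)
    trainable = [p for p in model.parameters() if p.requires_grad]
    trainable += head.parameters() + temp.parameters()
    named = [(n, p) for n, p in
             (model.named_parameters("model.") + head.named_parameters("head."))
             if p.requires_grad]
    opt = Adam(trainable, lr=train_cfg.lr)
    weights = _class_weights(train_batch.labels)

    def _loss_on(batch: EncodedBatch) -> tuple[Tensor, float, float]:
        logits, x_cls, h_cls = model(batch, use_gca=use_gca)
        task = cross_entropy(logits, batch.labels, weights)
        if beta > 0:
            cont = contrastive_loss(head(x_cls), head(h_cls), temp)
        else:
            cont = Tensor(0.0)
        reg = l2_regularization(named)
        total = total_loss(task, cont, reg, train_cfg.alpha, beta, train_cfg.gamma)
        return total, task.item(), cont.item()

    n = len(train_batch)
    best_loss, best_state, patience_left = np.inf, None, train_cfg.patience
    curve_rows = []
    for epoch in range(train_cfg.max_epochs):
        perm = rng.permutation(n)
        epoch_losses, epoch_task, epoch_cont = [], [], []
        accum = max(1, train_cfg.grad_accum)
        micro = max(1, train_cfg.batch_size // accum)
        for lo in range(0, n, train_cfg.batch_size):
            idx = perm[lo : lo + train_cfg.batch_size]
            opt.zero_grad()
            group_losses = []
            for mlo in range(0, len(idx), micro):
                frac = len(idx[mlo : mlo + micro]) / len(idx)
                total, task_val, cont_val = _loss_on(train_batch.subset(idx[mlo : mlo + micro]))
                loss = total * frac
                loss.backward()
                group_losses.append(loss.item())
                epoch_task.append(task_val)
                epoch_cont.append(cont_val)
            opt.step()
            temp.clamp_()
            epoch_losses.append(sum(group_losses))
        with no_grad():
            val_total, val_task, val_cont = _loss_on(val_batch)
            val_loss = val_total.item()
        if not np.isfinite(val_loss):
            raise DivergenceError(f"validation loss diverged at epoch {epoch}")
        curve_rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                           "train_task_loss": float(np.mean(epoch_task)),
                           "train_contrastive_loss": float(np.mean(epoch_cont)),
                           "val_loss": val_loss, "val_task_loss": val_task,
                           "val_contrastive_loss": val_cont, "tau": temp.value})
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = (model.state_dict(), head.state_dict(), temp.state_dict())
            patience_left = train_cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        model.load_state_dict(best_state[0])
        head.load_state_dict(best_state[1])
        temp.load_state_dict(best_state[2])
    return TrainedFold(model, head, temp, pd.DataFrame(curve_rows))


def train_model(cohort: Cohort, plan: FoldPlan, model_cfg: ModelConfig,
                train_cfg: TrainConfig, variant: str = "full",
                checkpoint_dir=None) -> tuple[MetricsReport, list[pd.DataFrame]]:
    """Train the fusion model across a fold plan; returns report + curves.

    With ``checkpoint_dir`` set, the best parameters of each fold are written
    as a parameter archive + JSON manifest under ``<dir>/fold<k>``.
    """
    report = MetricsReport()
    curves = []
    use_gca = variant != "no_cross_attention"
    for fold_id, (tr, va) in enumerate(plan.folds):
        pre = FoldPreprocessor.fit(cohort, tr)
        model = _build_model(cohort.schema, model_cfg, seed=train_cfg.seed + fold_id)
        train_batch = pre.encode(cohort, tr, model)
        val_batch = pre.encode(cohort, va, model)
        fitted = train_fold(train_batch, val_batch, model, model_cfg, train_cfg, variant)
        if checkpoint_dir is not None:
            from .checkpoint import save_checkpoint

            save_checkpoint(f"{checkpoint_dir}/fold{fold_id}", fitted.model,
                            fitted.head, fitted.temp, model_cfg, cohort.schema,
                            seed=train_cfg.seed + fold_id)
        preds = fitted.predict(val_batch, train_cfg.threshold, use_gca=use_gca)
        row = report.add_fold(val_batch.labels, preds, variant=variant, fold=fold_id)
        logger.info("variant=%s fold=%d acc=%.4f f1=%.4f", variant, fold_id,
                    row.accuracy, row.f1)
        curves.append(fitted.curves)
    return report, curves


# ---------------------------------------------------------------------------
# baselines (direct fusion + single modality)
# ---------------------------------------------------------------------------


def _binary_features(cohort: Cohort, pre: FoldPreprocessor, idx: np.ndarray) -> np.ndarray:
    from .schema import encode_binary

    rows = []
    for i in idx:
        r = impute_record(cohort.records[i], pre.stats, cohort.schema)
        rows.append(encode_binary(r, cohort.schema, pre.standardizer))
    return np.stack(rows)


def _pooled_text_features(cohort: Cohort, idx: np.ndarray, model_cfg: ModelConfig,
                          seed: int) -> np.ndarray:
    """Frozen seeded backbone, masked-mean pooled hidden states."""
    model = _build_model(cohort.schema, model_cfg, seed=seed)
    texts = [" ".join(cohort.records[i].text.get(u, "") for u in cohort.schema.text_units)
             for i in idx]
    feats = []
    with no_grad():
        for lo in range(0, len(texts), 256):
            ids, mask = model.tokenizer.encode_batch(texts[lo : lo + 256])
            hidden = model.backbone(ids, mask)
            feats.append(masked_mean(hidden, mask).data)
    return np.concatenate(feats)


def _tabular_classifier(kind: str, seed: int):
    if kind == "gbt":
        return HistGradientBoostingClassifier(random_state=seed)
    if kind == "fft":
        return MLPClassifier(hidden_layer_sizes=(64, 32), max_iter=500, random_state=seed)
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown tabular classifier {kind!r}")


def run_baseline(cohort: Cohort, plan: FoldPlan, model_cfg: ModelConfig,
                 train_cfg: TrainConfig, variant: str) -> MetricsReport:
    """Direct-fusion and single-modality baselines on the shared fold plan."""
    report = MetricsReport()
    for fold_id, (tr, va) in enumerate(plan.folds):
        pre = FoldPreprocessor.fit(cohort, tr)
        parts_train, parts_val = [], []
        if variant in ("direct_fusion_gbt", "direct_fusion_fft", "csv_only"):
            parts_train.append(_binary_features(cohort, pre, tr))
            parts_val.append(_binary_features(cohort, pre, va))
        if variant in ("direct_fusion_gbt", "direct_fusion_fft", "text_only"):
            seed = train_cfg.seed + fold_id
            parts_train.append(_pooled_text_features(cohort, tr, model_cfg, seed))
            parts_val.append(_pooled_text_features(cohort, va, model_cfg, seed))
        X_train = np.hstack(parts_train)
        X_val = np.hstack(parts_val)
        kind = {"direct_fusion_gbt": "gbt", "csv_only": "gbt",
                "direct_fusion_fft": "fft", "text_only": "logistic"}[variant]
        clf = _tabular_classifier(kind, train_cfg.seed + fold_id)
        clf.fit(X_train, cohort.labels()[tr])
        preds = (clf.predict_proba(X_val)[:, 1] > train_cfg.threshold).astype(int)
        report.add_fold(cohort.labels()[va], preds, variant=variant, fold=fold_id)
    return report


def run_ablation(cohort: Cohort, variants: list[str], model_cfg: ModelConfig,
                 train_cfg: TrainConfig, plan: FoldPlan | None = None) -> pd.DataFrame:
    """Ablation table with one averaged row per requested variant."""
    known = set(ABLATION_VARIANTS) | set(SINGLE_MODALITY_VARIANTS)
    unknown = set(variants) - known
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")
    plan = plan or stratified_kfold(cohort.labels(), train_cfg.n_folds, train_cfg.seed)
    rows = []
    for variant in variants:
        if variant in ("full", "no_contrastive", "no_cross_attention"):
            report, _ = train_model(cohort, plan, model_cfg, train_cfg, variant)
        else:
            report = run_baseline(cohort, plan, model_cfg, train_cfg, variant)
        for convention in ("mean_of_folds", "pooled_confusion"):
            agg = report.mean_of_folds() if convention == "mean_of_folds" else report.pooled()
            agg["variant"] = variant
            rows.append(agg)
    return pd.DataFrame(rows)


def single_modality_baselines(cohort: Cohort, model_cfg: ModelConfig,
                              train_cfg: TrainConfig, plan: FoldPlan | None = None) -> pd.DataFrame:
    plan = plan or stratified_kfold(cohort.labels(), train_cfg.n_folds, train_cfg.seed)
    return run_ablation(cohort, list(SINGLE_MODALITY_VARIANTS), model_cfg, train_cfg, plan)


def holdout_accuracy(cohort: Cohort, model_cfg: ModelConfig, train_cfg: TrainConfig,
                     variant: str = "full", val_fraction: float = 0.25) -> float:
    """Single stratified split accuracy (used by seed-median comparisons)."""
    labels = cohort.labels()
    idx = np.arange(len(labels))
    tr, va = train_test_split(idx, test_size=val_fraction, stratify=labels,
                              random_state=train_cfg.seed)
    plan = FoldPlan(folds=[(tr, va)], seed=train_cfg.seed)
    if variant in ("full", "no_contrastive", "no_cross_attention"):
        report, _ = train_model(cohort, plan, model_cfg, train_cfg, variant)
    else:
        report = run_baseline(cohort, plan, model_cfg, train_cfg, variant)
    return report.rows[0].accuracy
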