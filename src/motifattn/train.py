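"""Training loop with seed repeats and best-by-validation-AUC selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import (ModelSpec, SequenceModel, build_model, encode_batch,
                    total_loss, entropy_loss)
from .nn import Adam
from .simulate import LabeledSequenceSet

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 64
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    seeds: tuple[int, ...] = (0, 1, 2)
    patience: int = 5
    device: str = "cpu"  # kept for config compatibility; cpu only

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("at least one seed is required")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    model: SequenceModel
    best_seed: int
    best_val_auc: float
    history: list[dict] = field(default_factory=list)  # per seed, per epoch
    test_auc: float = float("nan")
    test_aupr: float = float("nan")


def _labels_2d(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    return labels[:, None] if labels.ndim == 1 else labels


def evaluate_classifier(model: SequenceModel, test: LabeledSequenceSet
                        ) -> tuple[float, float]:
    """AUC-ROC and AUPR on a held-out set; multi-label tasks average over
    labels, skipping any label with a single observed class."""
    if len(test) == 0:
        raise ValueError("empty evaluation set")
    out = model.forward(test.sequences)
    y = _labels_2d(test.labels)
    aucs, auprs = [], []
    for j in range(y.shape[1]):
        if len(np.unique(y[:, j])) < 2:
            logger.warning("label %d has a single class; skipped", j)
            continue
        aucs.append(roc_auc_score(y[:, j], out.predictions[:, j]))
        auprs.append(average_precision_score(y[:, j], out.predictions[:, j]))
    if not aucs:
        raise ValueError("no label with both classes present")
    return float(np.mean(aucs)), float(np.mean(auprs))


def _val_auc(model: SequenceModel, val: LabeledSequenceSet) -> float:
    out = model.forward(val.sequences)
    y = _labels_2d(val.labels)
    aucs = [roc_auc_score(y[:, j], out.predictions[:, j])
            for j in range(y.shape[1]) if len(np.unique(y[:, j])) == 2]
    return float(np.mean(aucs))


def train_one(spec: ModelSpec, cfg: TrainConfig, train: LabeledSequenceSet,
              val: LabeledSequenceSet, seed: int
              ) -> tuple[SequenceModel, float, list[dict]]:
    """Train one model with every RNG stream (init, shuffling) derived from
    ``seed``; returns the checkpoint with the best validation AUC."""
    rng = np.random.default_rng(seed)
    model = build_model(spec, train.seq_length,
                        seed=int(rng.integers(2 ** 31)))
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    x_all = encode_batch(train.sequences)
    y_all = _labels_2d(train.labels).astype(np.float64)
    n = len(train)
    lam = spec.entropy_lambda
    best_auc, best_state, best_epoch = -np.inf, None, -1
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, ents = [], []
        model.set_training(True)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits, attn, _ = model.forward_graph(x_all[idx])
            loss = total_loss(logits, y_all[idx], attn, lam)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, seed {seed}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            ents.append(entropy_loss(attn.data))
        val_auc = _val_auc(model, val)
        history.append(dict(seed=seed, epoch=epoch,
                            train_loss=float(np.mean(losses)),
                            attention_entropy=float(np.mean(ents)),
                            entropy_lambda=lam, val_auc=val_auc))
        logger.info("seed %d epoch %d loss %.4f entropy %.3f val_auc %.4f",
                    seed, epoch, np.mean(losses), np.mean(ents), val_auc)
        if val_auc > best_auc:
            best_auc, best_state, best_epoch = val_auc, model.state_dict(), epoch
        elif epoch - best_epoch >= cfg.patience:
            logger.info("early stop at epoch %d (seed %d)", epoch, seed)
            break
    model.load_state_dict(best_state)
    return model, best_auc, history


def train_model(spec: ModelSpec, cfg: TrainConfig,
                splits: tuple[LabeledSequenceSet, LabeledSequenceSet,
                              LabeledSequenceSet]) -> TrainResult:
    """Train once per seed and keep the across-seed best model, selected by
    validation AUC; test AUC/AUPR are computed for the selected model."""
    train, val, test = splits
    best: tuple[float, SequenceModel, int] | None = None
    history: list[dict] = []
    for seed in cfg.seeds:
        model, val_auc, h = train_one(spec, cfg, train, val, seed)
        history.extend(h)
        if best is None or val_auc > best[0]:
            best = (val_auc, model, seed)
    val_auc, model, seed = best
    result = TrainResult(model=model, best_seed=seed, best_val_auc=val_auc,
                         history=history)
    if len(test) > 0:
        result.test_auc, result.test_aupr = evaluate_classifier(model, test)
    return result


def sweep_configs(specs: list[ModelSpec], cfg: TrainConfig,
                  splits) -> "pd.DataFrame":
    """Simple configuration sweep: trains every spec with the same protocol
    and reports validation/test metrics, best first."""
    import pandas as pd

    rows = []
    for i, spec in enumerate(specs):
        result = train_model(spec, cfg, splits)
        rows.append(dict(config=i, architecture=spec.architecture,
                         n_filters=spec.n_filters,
                         entropy_lambda=spec.entropy_lambda,
                         use_rnn=spec.use_rnn,
                         best_seed=result.best_seed,
                         val_auc=result.best_val_auc,
                         test_auc=result.test_auc,
                         test_aupr=result.test_aupr))
    return pd.DataFrame(rows).sort_values(
        "val_auc", ascending=False).reset_index(drop=True)
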