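"""Optimization loop: AdamW, weighted label loss + adversarial domain loss,
early stopping on validation AUC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import (
    ModelConfig,
    SeizureDomainNet,
    domain_ce_from_logits,
    save_checkpoint,
    weighted_ce_from_logits,
)
from .nn import AdamW
from .preprocess import (
    LeakageError,
    NormStats,
    WindowSet,
    apply_zscore,
    fit_zscore,
    stft_logmag,
)

__all__ = ["TrainConfig", "TrainLog", "TrainedModel", "lambda_schedule", "train_model"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    lambda_mode: str = "schedule"       # "constant" | "schedule"
    lambda_constant: float = 1.0
    domain_loss_weight: float = 1.0

    def __post_init__(self):
        if min(self.lr, self.weight_decay, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("lr, weight_decay, batch_size, max_epochs and patience "
                             "must all be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.lambda_mode not in ("constant", "schedule"):
            raise ValueError("lambda_mode must be 'constant' or 'schedule'")


@dataclass
class TrainLog:
    rows: list[dict] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df["stopped_early"] = self.stopped_early
        df["best_epoch"] = self.best_epoch
        return df


@dataclass
class TrainedModel:
    """Best-validation-AUC checkpoint plus everything needed to reuse it."""

    model: SeizureDomainNet
    norm_stats: NormStats
    domain_map: dict[str, int]
    val_auc: float

    def save(self, path: str, extra: dict | None = None) -> None:
        save_checkpoint(path, self.model, self.norm_stats, self.domain_map,
                        extra={"val_auc": self.val_auc, **(extra or {})})


def lambda_schedule(progress: float, mode: str = "schedule",
                    constant: float = 1.0) -> float:
    """Adversarial coefficient: constant, or the standard warm-up ramp
    2 / (1 + exp(-10 p)) - 1 over training progress p in [0, 1]."""
    if not 0.0 <= progress <= 1.0:
        warnings.warn(f"training progress {progress} outside [0, 1]; clamping",
                      stacklevel=2)
        progress = min(max(progress, 0.0), 1.0)
    if mode == "constant":
        return float(constant)
    if mode == "schedule":
        return float(2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0)
    raise ValueError(f"unknown lambda mode {mode!r}")


def _prepare(train_windows: WindowSet, val_windows: WindowSet):
    train_subjects = set(map(str, train_windows.subject_ids))
    val_subjects = set(map(str, val_windows.subject_ids))
    overlap = train_subjects & val_subjects
    if overlap:
        raise LeakageError(f"train and validation subject sets overlap: {sorted(overlap)}")
    spec_train = stft_logmag(train_windows)
    stats = fit_zscore(spec_train, train_windows.subject_ids)
    x_train = apply_zscore(spec_train, stats).tensor.astype(np.float32)
    x_val = apply_zscore(stft_logmag(val_windows), stats, val_windows.subject_ids,
                         role="eval").tensor.astype(np.float32)
    domain_map = {sid: i for i, sid in enumerate(sorted(train_subjects))}
    d_train = np.array([domain_map[str(s)] for s in train_windows.subject_ids])
    return x_train, x_val, stats, domain_map, d_train


def _val_auc(model: SeizureDomainNet, x_val: np.ndarray, y_val: np.ndarray) -> float:
    probs = model.predict_proba(x_val)
    if len(np.unique(y_val)) < 2:
        warnings.warn("validation labels are single-class; AUC undefined, using 0.5",
                      stacklevel=2)
        return 0.5
    return float(roc_auc_score(y_val, probs))


def train_model(train_windows: WindowSet, val_windows: WindowSet,
                mcfg: ModelConfig, tcfg: TrainConfig,
                val_metric_fn=None) -> tuple[TrainedModel, TrainLog]:
    """Train with total loss L_label + domain_loss_weight * L_domain (GRL inside
    the domain path); return the best-validation-AUC model and the epoch log.

    ``val_metric_fn(model, x_val, y_val) -> float`` may replace the AUC monitor
    (used by tests to script early-stopping behaviour).
    """
    x_train, x_val, stats, domain_map, d_train = _prepare(train_windows, val_windows)
    if len(domain_map) < 2 and tcfg.domain_loss_weight > 0:
        raise ValueError("adversarial training requires >= 2 training subjects")
    mcfg = replace(mcfg, n_domains=max(len(domain_map), 2))
    y_train = np.asarray(train_windows.labels)
    y_val = np.asarray(val_windows.labels)

    model = SeizureDomainNet(mcfg, seed=tcfg.seed)
    opt = AdamW(model.parameters(), lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(tcfg.seed, spawn_key=(7,)))
    metric = val_metric_fn or _val_auc

    log = TrainLog()
    best_auc = -np.inf
    best_state: dict | None = None
    epochs_since_best = 0
    n = x_train.shape[0]

    for epoch in range(1, tcfg.max_epochs + 1):
        progress = (epoch - 1) / max(1, tcfg.max_epochs - 1)
        lam = lambda_schedule(progress, tcfg.lambda_mode, tcfg.lambda_constant)
        order = shuffle_rng.permutation(n)
        label_losses, domain_losses = [], []
        model.train()
        for i in range(0, n, tcfg.batch_size):
            idx = order[i:i + tcfg.batch_size]
            out = model.forward(x_train[idx], lam=lam)
            l_y = weighted_ce_from_logits(out.label_logits_t, y_train[idx], mcfg.w_pos)
            l_d = domain_ce_from_logits(out.domain_logits_t, d_train[idx])
            loss = l_y + tcfg.domain_loss_weight * l_d
            opt.zero_grad()
            loss.backward()
            opt.step()
            label_losses.append(float(l_y.data))
            domain_losses.append(float(l_d.data))

        val_auc = float(metric(model, x_val, y_val))
        log.rows.append({"epoch": epoch, "train_label_loss": float(np.mean(label_losses)),
                         "train_domain_loss": float(np.mean(domain_losses)),
                         "val_auc": val_auc, "lambda": lam})
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            log.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= tcfg.patience:
                log.stopped_early = True
                break

    assert best_state is not None
    model.load_state_dict(best_state)
    model.eval()
    return TrainedModel(model=model, norm_stats=stats, domain_map=domain_map,
                        val_auc=float(best_auc)), log
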