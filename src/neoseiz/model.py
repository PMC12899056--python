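"""The seizure-detection network.

A weight-shared single-channel CNN encodes each electrode's spectrogram
(channels folded into the batch axis), a bidirectional LSTM scans the 18
montage channels as a fixed spatial sequence, attention pooling (or mean
pooling for the ablated variant) aggregates per-channel features into one
512-dim vector, and two heads consume it: a label predictor and a
gradient-reversed domain classifier over training-subject identities.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .preprocess import BIPOLAR_NAMES, NormStats, N_FREQ_BINS, N_TIME_FRAMES

__all__ = [
    "ModelConfig",
    "ModelOutputs",
    "fold_channels",
    "unfold_channels",
    "CICNNEncoder",
    "SpatialBiLSTM",
    "AttentionPool",
    "MeanPool",
    "SeizureDomainNet",
    "weighted_ce_loss",
    "weighted_ce_from_logits",
    "domain_ce_from_logits",
    "save_checkpoint",
    "load_checkpoint",
]

#: spatial size the encoder pools to before flattening; together with the
#: stage-3 width (4 x base_width) this fixes the flattened feature length
#: (4 x 64) x (3 x 2) = 1536 at the default width.
_POOL_HW = (3, 2)


@dataclass
class ModelConfig:
    n_channels: int = 18
    base_width: int = 64          # stem width of the truncated residual encoder
    lstm_hidden: int = 256
    n_domains: int = 2
    w_pos: float = 2.5
    dropout_p: float = 0.3
    attention_hidden: int = 128
    head_hidden: int = 128
    use_attention: bool = True

    @property
    def cnn_out_dim(self) -> int:
        return 4 * self.base_width * _POOL_HW[0] * _POOL_HW[1]

    @property
    def pooled_dim(self) -> int:
        return 2 * self.lstm_hidden

    def __post_init__(self):
        if self.n_channels != 18:
            raise ValueError("the montage contract fixes n_channels at 18")
        if self.n_domains < 2:
            raise ValueError("domain classification requires n_domains >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelOutputs:
    seizure_prob: np.ndarray      # N
    domain_logits: np.ndarray     # N x n_domains
    attention: np.ndarray         # N x 18
    pooled: np.ndarray            # N x pooled_dim
    label_logits_t: Tensor = field(repr=False, default=None)
    domain_logits_t: Tensor = field(repr=False, default=None)


def fold_channels(x: np.ndarray) -> np.ndarray:
    """(N, C, F, T) -> (N*C, 1, F, T); row n*C + c holds channel c of sample n."""
    if x.ndim != 4:
        raise ValueError(f"expected 4-D tensor, got shape {x.shape}")
    n, c, f, t = x.shape
    return x.reshape(n * c, 1, f, t)


def unfold_channels(x: np.ndarray, n_channels: int) -> np.ndarray:
    """(N*C, D) -> (N, C, D); inverse of :func:`fold_channels` after encoding."""
    total = x.shape[0]
    if total % n_channels:
        raise ValueError(f"leading dimension {total} not divisible by {n_channels}")
    return x.reshape(total // n_channels, n_channels, *x.shape[1:])


class _BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class CICNNEncoder(nn.Module):
    """Truncated residual encoder applied to single-channel spectrograms.

    Stem (7x7/2 conv + 3x3/2 max-pool) followed by three residual stages of
    widths w, 2w, 4w, adaptive average pooling to 3x2 and flattening; the
    default width w=64 yields the 1536-dim per-channel feature contract.
    """

    def __init__(self, base_width: int, rng: np.random.Generator):
        super().__init__()
        w = base_width
        self.stem_conv = nn.Conv2d(1, w, 7, rng, stride=2, padding=3)
        self.stem_bn = nn.BatchNorm2d(w)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.layer1 = nn.Sequential(_BasicBlock(w, w, 1, rng), _BasicBlock(w, w, 1, rng))
        self.layer2 = nn.Sequential(_BasicBlock(w, 2 * w, 2, rng), _BasicBlock(2 * w, 2 * w, 1, rng))
        self.layer3 = nn.Sequential(_BasicBlock(2 * w, 4 * w, 2, rng), _BasicBlock(4 * w, 4 * w, 1, rng))
        self.avgpool = nn.AdaptiveAvgPool2d(_POOL_HW)
        self.out_dim = 4 * w * _POOL_HW[0] * _POOL_HW[1]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 1:
            raise ValueError("encoder expects folded single-channel input")
        out = self.pool(self.stem_bn(self.stem_conv(x)).relu())
        out = self.layer3(self.layer2(self.layer1(out)))
        out = self.avgpool(out)
        return out.reshape(out.shape[0], self.out_dim)


class SpatialBiLSTM(nn.Module):
    """Bidirectional LSTM over the fixed 18-channel montage sequence."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator,
                 seq_len: int = 18):
        super().__init__()
        self.lstm = nn.BiLSTM(input_dim, hidden, rng)
        self.seq_len = seq_len

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.seq_len:
            raise ValueError(f"expected sequence length {self.seq_len}, got {x.shape[1]}")
        return self.lstm(x)  # (N, seq, 2*hidden)


class AttentionPool(nn.Module):
    """Gated attention pooling: e_i = v^T tanh(W h_i + b), alpha = softmax(e)."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(dim, hidden, rng)
        self.v = nn.Linear(hidden, 1, rng, bias=False)

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        scores = self.v(self.proj(h).tanh())            # (N, C, 1)
        alpha = nn.softmax(scores[:, :, 0], axis=1)     # (N, C)
        n, c, d = h.shape
        z = (h * alpha.reshape(n, c, 1)).sum(axis=1)    # (N, D)
        return z, alpha


class MeanPool(nn.Module):
    """Unweighted average over channels (ablation substitute for attention)."""

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        n, c, _ = h.shape
        z = h.mean(axis=1)
        alpha = Tensor(np.full((n, c), 1.0 / c, dtype=h.data.dtype))
        return z, alpha


class _MLPHead(nn.Module):
    def __init__(self, in_dim: int, hidden: int, out_dim: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.drop = nn.Dropout(dropout_p, rng)
        self.fc2 = nn.Linear(hidden, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu()))


class SeizureDomainNet(nn.Module):
    """Shared backbone with label-prediction and adversarial domain heads."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
        self.cfg = cfg
        self.encoder = CICNNEncoder(cfg.base_width, rng)
        self.bilstm = SpatialBiLSTM(cfg.cnn_out_dim, cfg.lstm_hidden, rng,
                                    seq_len=cfg.n_channels)
        if cfg.use_attention:
            self.pool = AttentionPool(cfg.pooled_dim, cfg.attention_hidden, rng)
        else:
            self.pool = MeanPool()
        self.label_head = _MLPHead(cfg.pooled_dim, cfg.head_hidden, 2, cfg.dropout_p, rng)
        self.domain_head = _MLPHead(cfg.pooled_dim, cfg.head_hidden, cfg.n_domains,
                                    0.0, rng)

    def backbone(self, x: np.ndarray) -> tuple[Tensor, Tensor]:
        """Spectrogram batch (N, 18, F, T) -> (pooled features, attention weights)."""
        if x.ndim != 4 or x.shape[1] != self.cfg.n_channels:
            raise ValueError(f"expected (N, {self.cfg.n_channels}, {N_FREQ_BINS}, "
                             f"{N_TIME_FRAMES}) input, got {x.shape}")
        folded = Tensor(fold_channels(np.ascontiguousarray(x)))
        feats = self.encoder(folded)                               # (N*C, D_cnn)
        seq = feats.reshape(x.shape[0], self.cfg.n_channels, self.cfg.cnn_out_dim)
        spatial = self.bilstm(seq)                                 # (N, C, 512)
        return self.pool(spatial)

    def forward(self, x: np.ndarray, lam: float = 0.0) -> ModelOutputs:
        z, alpha = self.backbone(x)
        label_logits = self.label_head(z)
        domain_logits = self.domain_head(nn.grad_reverse(z, lam))
        prob = nn.softmax(label_logits, axis=1)
        return ModelOutputs(
            seizure_prob=prob.data[:, 1].copy(),
            domain_logits=domain_logits.data.copy(),
            attention=alpha.data.copy(),
            pooled=z.data.copy(),
            label_logits_t=label_logits,
            domain_logits_t=domain_logits,
        )

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic eval-mode seizure probabilities."""
        was_training = self.training
        self.eval()
        probs = [self.forward(x[i:i + batch_size]).seizure_prob
                 for i in range(0, x.shape[0], batch_size)]
        self.train(was_training)
        return np.concatenate(probs) if probs else np.empty(0)


# -- losses ---------------------------------------------------------------------

def weighted_ce_loss(probs: np.ndarray, labels: np.ndarray, w_pos: float = 2.5,
                     reduction: str = "sum") -> float:
    """Class-weighted binary cross-entropy from seizure probabilities.

    L = -sum_i [ w_pos * y_i * ln p_i + (1 - y_i) * ln (1 - p_i) ]; probabilities
    are clamped at 1e-7. ``reduction`` is "sum" (the reference form) or "mean".
    """
    probs = np.clip(np.asarray(probs, dtype=np.float64), 1e-7, 1.0 - 1e-7)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("empty batch")
    terms = w_pos * labels * np.log(probs) + (1.0 - labels) * np.log(1.0 - probs)
    total = -terms.sum()
    return float(total / probs.size) if reduction == "mean" else float(total)


def weighted_ce_from_logits(logits: Tensor, labels: np.ndarray, w_pos: float = 2.5) -> Tensor:
    """Differentiable batch-mean weighted cross-entropy over 2-way logits."""
    n = logits.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    logp = nn.log_softmax(logits, axis=1)
    y = np.asarray(labels, dtype=np.float32)
    w = Tensor(np.stack([(1.0 - y), w_pos * y], axis=1).astype(np.float32))
    return -(logp * w).sum() * (1.0 / n)


def domain_ce_from_logits(logits: Tensor, domain_idx: np.ndarray) -> Tensor:
    """Batch-mean multi-class cross-entropy for the domain classifier."""
    n, k = logits.shape
    logp = nn.log_softmax(logits, axis=1)
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), np.asarray(domain_idx, dtype=int)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


# -- checkpoints ------------------------------------------------------------------

def save_checkpoint(path: str, model: SeizureDomainNet, norm_stats: NormStats | None,
                    domain_map: dict[str, int] | None, extra: dict | None = None) -> None:
    """Weights blob (npz) + JSON sidecar with config, stats and domain index map."""
    os.makedirs(path, exist_ok=True)
    np.savez(os.path.join(path, "weights.npz"), **model.state_dict())
    sidecar = {
        "model_config": model.cfg.to_dict(),
        "norm_stats": norm_stats.to_dict() if norm_stats else None,
        "montage_order": list(BIPOLAR_NAMES),
        "domain_map": domain_map,
        "extra": extra or {},
    }
    with open(os.path.join(path, "checkpoint.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str) -> tuple[SeizureDomainNet, dict]:
    with open(os.path.join(path, "checkpoint.json")) as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig(**sidecar["model_config"])
    model = SeizureDomainNet(cfg)
    with np.load(os.path.join(path, "weights.npz")) as blob:
        model.load_state_dict({k: blob[k] for k in blob.files})
    model.eval()
    return model, sidecar
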