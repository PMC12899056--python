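"""Window-level metrics, subject-level stratified 5-fold CV, the source-data
scaling experiment, and the four-variant ablation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .consensus import AnnotationSet, consensus_per_second
from .data import EEGRecording
from .model import ModelConfig
from .preprocess import WindowSet, derive_bipolar_montage, downsample_signal, segment_windows
from .training import TrainConfig, TrainedModel, train_model

__all__ = [
    "ConfusionCounts",
    "MetricsEntry",
    "MetricsReport",
    "FoldPlan",
    "ExperimentGrid",
    "compute_metrics",
    "make_group_folds",
    "subject_windows",
    "run_cross_validation",
    "run_data_scaling",
    "run_ablation",
    "export_attention_map",
    "variant_settings",
    "UnsupportedVariantError",
]

VARIANTS = ("baseline", "att", "da", "full")


class UnsupportedVariantError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsEntry:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float | None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1, "auc": self.auc}


@dataclass
class MetricsReport:
    per_fold: list[MetricsEntry] = field(default_factory=list)

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(e, name) for e in self.per_fold], dtype=float)

    def mean(self) -> dict[str, float]:
        return {k: float(np.nanmean(self._values(k)))
                for k in ("accuracy", "sensitivity", "specificity", "f1", "auc")}

    def std(self) -> dict[str, float]:
        return {k: float(np.nanstd(self._values(k)))
                for k in ("accuracy", "sensitivity", "specificity", "f1", "auc")}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([e.as_dict() for e in self.per_fold])
        df.index.name = "fold"
        return df


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: dict[str, int]
    stratified: bool = True

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f == fold)


@dataclass(frozen=True)
class ExperimentGrid:
    gamma_values: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 1.0)
    variants: tuple[str, ...] = VARIANTS
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if any(not 0.0 < g <= 1.0 for g in self.gamma_values):
            raise ValueError("gamma values must lie in (0, 1]")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> tuple[ConfusionCounts, MetricsEntry]:
    """Threshold the scores into a confusion matrix; AUC is threshold-free.

    With single-class labels the AUC is undefined and reported as ``None``;
    the remaining metrics are still returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("need at least one evaluated window")
    preds = (scores >= threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    auc = (float(roc_auc_score(labels, scores))
           if len(np.unique(labels)) == 2 else None)
    entry = MetricsEntry(
        accuracy=(tp + tn) / counts.total,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        f1=2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        auc=auc,
    )
    return counts, entry


def make_group_folds(selection, k: int = 5, seed: int = 0) -> FoldPlan:
    """Subject-level stratified folds: shuffle within each group, deal round-robin.

    ``selection`` is either a DataFrame with subject_id/group columns (only
    ``selected`` rows are used when that column exists) or a list of
    (subject_id, group) pairs.
    """
    if isinstance(selection, pd.DataFrame):
        df = selection[selection["selected"]] if "selected" in selection else selection
        pairs = list(zip(df["subject_id"].astype(str), df["group"]))
    else:
        pairs = [(str(s), g) for s, g in selection]
    assignments: dict[str, int] = {}
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13,)))
    for group in sorted({g for _, g in pairs}):
        members = sorted(s for s, g in pairs if g == group)
        if len(members) < k:
            raise ValueError(f"group {group!r} has {len(members)} subjects; "
                             f"need at least {k} for {k} folds")
        rng.shuffle(members)
        for i, sid in enumerate(members):
            assignments[sid] = i % k
    return FoldPlan(k=k, assignments=assignments, stratified=True)


def subject_windows(rec: EEGRecording, role: str) -> WindowSet:
    """Full per-subject pipeline: consensus -> montage -> 128 Hz -> windows."""
    if rec.annotations is None:
        raise ValueError(f"recording {rec.subject_id!r} has no annotations")
    track = consensus_per_second(AnnotationSet(rec.subject_id, rec.annotations))
    bipolar = downsample_signal(derive_bipolar_montage(rec))
    return segment_windows(bipolar, track.consensus, role)


def _stratified_window_subset(w: WindowSet, fraction: float | None,
                              max_windows: int | None, seed: int) -> WindowSet:
    """Random class-stratified subset; used for gamma-scaling and CPU budgets."""
    n = len(w)
    target = n
    if fraction is not None:
        target = int(round(fraction * n))
    if max_windows is not None:
        target = min(target, max_windows)
    if target >= n:
        return w
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(29,)))
    labels = np.asarray(w.labels)
    keep: list[np.ndarray] = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        n_cls = int(round(target * len(cls_idx) / n))
        n_cls = max(min(n_cls, len(cls_idx)), 1)
        keep.append(rng.choice(cls_idx, size=n_cls, replace=False))
    idx = np.sort(np.concatenate(keep))
    return w.subset(idx)


def _split_val_subjects(train_sids: list[str], groups: dict[str, str],
                        val_frac: float, seed: int) -> tuple[list[str], list[str]]:
    """Hold out ~val_frac of training subjects (>=1 per group) for early stopping."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(31,)))
    val: list[str] = []
    for group in sorted({groups[s] for s in train_sids}):
        members = sorted(s for s in train_sids if groups[s] == group)
        rng.shuffle(members)
        n_val = max(1, int(round(val_frac * len(members))))
        val.extend(members[:n_val])
    fit = [s for s in train_sids if s not in set(val)]
    return fit, val


def train_eval_split(recordings: dict[str, EEGRecording], groups: dict[str, str],
                     train_sids: list[str], test_sids: list[str],
                     mcfg: ModelConfig, tcfg: TrainConfig,
                     val_frac: float = 0.2, gamma: float | None = None,
                     max_train_windows: int | None = None,
                     ) -> tuple[TrainedModel, MetricsEntry, dict]:
    """Train on ``train_sids`` (with a subject-held-out validation sub-split)
    and evaluate on ``test_sids``' non-overlapping eval windows."""
    fit_sids, val_sids = _split_val_subjects(train_sids, groups, val_frac, tcfg.seed)
    train_w = WindowSet.concatenate([subject_windows(recordings[s], "train")
                                     for s in fit_sids])
    train_w = _stratified_window_subset(train_w, gamma, max_train_windows, tcfg.seed)
    if len(np.unique(train_w.labels)) < 2:
        raise ValueError("training subset contains a single class; increase gamma "
                         "or the window budget")
    val_w = WindowSet.concatenate([subject_windows(recordings[s], "eval")
                                   for s in val_sids])
    test_w = WindowSet.concatenate([subject_windows(recordings[s], "eval")
                                    for s in test_sids])
    assert not (set(fit_sids) & set(test_sids)), "CV purity violated"
    trained, log = train_model(train_w, val_w, mcfg, tcfg)
    x_test = _normalized_tensor(trained, test_w)
    probs = trained.model.predict_proba(x_test)
    counts, entry = compute_metrics(probs, test_w.labels)
    info = {"fit_subjects": fit_sids, "val_subjects": val_sids,
            "test_subjects": list(test_sids), "n_train_windows": len(train_w),
            "counts": counts, "log": log}
    return trained, entry, info


def _normalized_tensor(trained: TrainedModel, w: WindowSet) -> np.ndarray:
    from .preprocess import apply_zscore, stft_logmag

    return apply_zscore(stft_logmag(w), trained.norm_stats, w.subject_ids,
                        role="eval").tensor.astype(np.float32)


def run_cross_validation(cohort: list[EEGRecording], mcfg: ModelConfig,
                         tcfg: TrainConfig, plan: FoldPlan,
                         groups: dict[str, str] | None = None,
                         max_train_windows: int | None = None,
                         folds: list[int] | None = None) -> MetricsReport:
    """Train on k-1 folds of subjects, evaluate the held-out fold, aggregate."""
    recordings = {r.subject_id: r for r in cohort}
    missing = set(plan.assignments) - set(recordings)
    if missing:
        raise ValueError(f"fold plan references unknown subjects: {sorted(missing)}")
    if groups is None:
        groups = {r.subject_id: ("seizure" if r.truth_mask is not None
                                 and r.truth_mask.any() else "non_seizure")
                  for r in cohort}
    report = MetricsReport()
    for fold in (folds if folds is not None else range(plan.k)):
        test_sids = plan.fold_subjects(fold)
        train_sids = sorted(set(plan.assignments) - set(test_sids))
        _, entry, _ = train_eval_split(recordings, groups, train_sids, test_sids,
                                       mcfg, tcfg, max_train_windows=max_train_windows)
        report.per_fold.append(entry)
    return report


def run_data_scaling(cohort: list[EEGRecording], grid: ExperimentGrid,
                     mcfg: ModelConfig, tcfg: TrainConfig, plan: FoldPlan,
                     test_fold: int = 0,
                     max_train_windows: int | None = None) -> dict[float, MetricsEntry]:
    """Retrain from scratch on stratified gamma-fractions of the source windows
    while the target-domain test fold stays fixed."""
    recordings = {r.subject_id: r for r in cohort}
    groups = {r.subject_id: ("seizure" if r.truth_mask is not None
                             and r.truth_mask.any() else "non_seizure")
              for r in cohort}
    test_sids = plan.fold_subjects(test_fold)
    train_sids = sorted(set(plan.assignments) - set(test_sids))
    results: dict[float, MetricsEntry] = {}
    for gamma in grid.gamma_values:
        _, entry, _ = train_eval_split(recordings, groups, train_sids, test_sids,
                                       mcfg, tcfg, gamma=gamma,
                                       max_train_windows=max_train_windows)
        results[gamma] = entry
    return results


def variant_settings(variant: str, mcfg: ModelConfig,
                     tcfg: TrainConfig) -> tuple[ModelConfig, TrainConfig]:
    """baseline = mean pool + lambda 0; att = attention + lambda 0;
    da = mean pool + lambda > 0; full = attention + lambda > 0."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    use_attention = variant in ("att", "full")
    adversarial = variant in ("da", "full")
    mcfg = replace(mcfg, use_attention=use_attention)
    if not adversarial:
        tcfg = replace(tcfg, lambda_mode="constant", lambda_constant=0.0)
    return mcfg, tcfg


def run_ablation(cohort: list[EEGRecording], variants: tuple[str, ...],
                 mcfg: ModelConfig, tcfg: TrainConfig, plan: FoldPlan,
                 seeds: tuple[int, ...] = (0,), folds: list[int] | None = None,
                 max_train_windows: int | None = None) -> dict[str, MetricsReport]:
    """Paired-variant comparison: the same seed list and fold plan per variant."""
    results: dict[str, MetricsReport] = {}
    for variant in variants:
        v_mcfg, v_tcfg = variant_settings(variant, mcfg, tcfg)
        report = MetricsReport()
        for seed in seeds:
            seeded = replace(v_tcfg, seed=seed)
            fold_report = run_cross_validation(cohort, v_mcfg, seeded, plan,
                                               max_train_windows=max_train_windows,
                                               folds=folds)
            report.per_fold.extend(fold_report.per_fold)
        results[variant] = report
    return results


def export_attention_map(trained: TrainedModel, windows: WindowSet) -> pd.DataFrame:
    """Per-window attention rows (18 columns) plus the uniform 1/18 reference."""
    if not trained.model.cfg.use_attention:
        raise UnsupportedVariantError("checkpoint uses mean pooling; no attention "
                                      "weights to export")
    x = _normalized_tensor(trained, windows)
    trained.model.eval()
    rows = []
    for i in range(0, x.shape[0], 256):
        rows.append(trained.model.forward(x[i:i + 256]).attention)
    alphas = np.concatenate(rows) if rows else np.empty((0, trained.model.cfg.n_channels))
    df = pd.DataFrame(alphas, columns=[f"ch{i}" for i in range(alphas.shape[1])])
    df.insert(0, "subject_id", windows.subject_ids)
    df.insert(1, "start_time_s", windows.start_times_s)
    df.attrs["uniform_reference"] = 1.0 / trained.model.cfg.n_channels
    return df
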