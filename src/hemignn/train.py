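"""Cross-subject leave-one-pair-out protocol, metrics, and statistics.

Subjects are matched into MDD-HC pairs; each fold holds out every window of
one pair and trains on the rest, with a window-level stratified 80/20
train/validation split.  Training uses Adam with cosine-annealed learning
rate, best-validation-accuracy checkpointing and early stopping on the
validation loss.  Metrics are window-level confusion counts: accuracy,
sensitivity and specificity as percentages and the F-measure
2*TP / (FP + FN + 2*TP); runs are compared with one-sided paired t-tests on
fold-wise accuracies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    EEGRecording,
    WindowSample,
    bandpass_notch,
    extract_middle_segment,
    load_cohort,
    make_windows,
)
from .model import HemiGraphNet, ModelConfig
from .nn import Adam, CosineAnnealingLR
from .nn import tensor as T
from .nn.tensor import no_grad

__all__ = [
    "TrainConfig",
    "FoldResult",
    "EvalSummary",
    "TrainingError",
    "ProtocolError",
    "make_lopo_folds",
    "split_train_val",
    "train_fold",
    "compute_metrics",
    "paired_one_sided_t_test",
    "TTestResult",
    "prepare_windows",
    "windows_to_arrays",
    "run_experiment",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f_measure")

logger = logging.getLogger("hemignn.train")


class TrainingError(RuntimeError):
    pass


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    t_max: int = 50  # cosine annealing period (epochs)
    eta_min: float = 1e-6
    max_epochs: int = 50
    batch_size: int = 64
    early_stop_patience: int = 10  # epochs without val-loss improvement
    val_fraction: float = 0.2
    val_split: str = "window"  # window (protocol-faithful) | subject
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.val_split not in ("window", "subject"):
            raise ValueError("val_split must be 'window' or 'subject'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldResult:
    held_out_pair: tuple[str, str]  # (MDD subject, HC subject)
    confusion: dict[str, int]  # tp, tn, fp, fn over test windows
    metrics: dict[str, float]
    best_epoch: int
    epochs_run: int

    def to_dict(self) -> dict:
        return {
            "held_out_pair": list(self.held_out_pair),
            "confusion": dict(self.confusion),
            "metrics": {k: _jsonable(v) for k, v in self.metrics.items()},
            "best_epoch": self.best_epoch,
            "epochs_run": self.epochs_run,
        }


@dataclass
class EvalSummary:
    folds: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]
    aggregated_confusion: dict[str, int]
    pooled_metrics: dict[str, float]
    model_config: dict
    train_config: dict

    def to_dict(self) -> dict:
        return {
            "folds": [f.to_dict() for f in self.folds],
            "mean": {k: _jsonable(v) for k, v in self.mean.items()},
            "std": {k: _jsonable(v) for k, v in self.std.items()},
            "aggregated_confusion": dict(self.aggregated_confusion),
            "pooled_metrics": {k: _jsonable(v) for k, v in self.pooled_metrics.items()},
            "model_config": self.model_config,
            "train_config": self.train_config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def save(self, out_dir: str | Path) -> None:
        """Write summary JSON plus a per-fold CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(self.to_json())
        rows = []
        for f in self.folds:
            row = {
                "mdd_subject": f.held_out_pair[0],
                "hc_subject": f.held_out_pair[1],
                **f.confusion,
                **f.metrics,
                "best_epoch": f.best_epoch,
                "epochs_run": f.epochs_run,
            }
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "folds.csv", index=False)


def _jsonable(v) -> float:
    v = float(v)
    return None if np.isnan(v) else v


# -- protocol -----------------------------------------------------------------

def make_lopo_folds(
    subjects: list[tuple[str, str]], seed: int = 0
) -> list[tuple[str, str]]:
    """Match MDD and HC subjects into held-out pairs (seeded random matching).

    ``subjects`` is a list of (subject_id, group).  Returns one
    (mdd_id, hc_id) pair per fold; requires balanced groups.
    """
    mdd = sorted(s for s, g in subjects if g == "MDD")
    hc = sorted(s for s, g in subjects if g == "HC")
    if len(mdd) != len(hc):
        raise ProtocolError(
            f"unbalanced groups: {len(mdd)} MDD vs {len(hc)} HC subjects"
        )
    if not mdd:
        raise ProtocolError("no subjects")
    rng = np.random.default_rng(seed)
    hc = [hc[i] for i in rng.permutation(len(hc))]
    return list(zip(mdd, hc))


def split_train_val(
    y: np.ndarray,
    val_fraction: float = 0.2,
    seed: int = 0,
    subjects: np.ndarray | None = None,
    level: str = "window",
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split of the training pool; returns (train, val) indices.

    ``level="window"`` (protocol-faithful) splits individual windows, which
    mixes a subject's windows across train and validation.  ``level="subject"``
    holds out whole subjects per class instead — cleaner, but a deviation, so
    it logs a warning.
    """
    if len(y) < 2:
        raise ProtocolError("need at least 2 windows to split")
    rng = np.random.default_rng(seed)
    if level == "subject":
        if subjects is None:
            raise ProtocolError("subject-level split needs subject ids")
        logger.warning(
            "subject-level validation split is a deviation from the "
            "window-level protocol; results are not directly comparable"
        )
        val_subjects = []
        for cls in np.unique(y):
            sids = sorted(set(subjects[y == cls]))
            sids = [sids[i] for i in rng.permutation(len(sids))]
            n_val = max(1, int(round(val_fraction * len(sids))))
            val_subjects.extend(sids[:n_val])
        val_mask = np.isin(subjects, val_subjects)
        return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(val_fraction * len(idx)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


# -- metrics and statistics -----------------------------------------------------

def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Window-level metrics; zero-denominator entries are NaN, not errors.

    Accuracy, sensitivity (MDD recall) and specificity are percentages;
    the F-measure 2*TP / (FP + FN + 2*TP) is a fraction.
    """
    counts = dict(tp=tp, tn=tn, fp=fp, fn=fn)
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"negative confusion counts: {counts}")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": 100.0 * (tp + tn) / total,
        "sensitivity": 100.0 * ratio(tp, tp + fn),
        "specificity": 100.0 * ratio(tn, tn + fp),
        "f_measure": ratio(2 * tp, fp + fn + 2 * tp),
    }


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool  # zero-variance differences: p by sign convention
    n: int


def paired_one_sided_t_test(a, b) -> TTestResult:
    """Upper-tail paired t-test of H1: mean(a - b) > 0 on fold-wise values."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        p = 0.5 if mean == 0 else (0.0 if mean > 0 else 1.0)
        t_stat = 0.0 if mean == 0 else np.copysign(np.inf, mean)
        return TTestResult(t=float(t_stat), p=p, degenerate=True, n=n)
    t_stat = mean / (sd / np.sqrt(n))
    return TTestResult(
        t=float(t_stat), p=float(stats.t.sf(t_stat, df=n - 1)), degenerate=False, n=n
    )


def compare_runs(a: "EvalSummary", b: "EvalSummary", metric: str = "accuracy") -> TTestResult:
    """One-sided paired t-test that run ``a`` beats run ``b`` fold-wise.

    Folds are matched by held-out pair, so both runs must use the same cohort
    and pairing.
    """
    pairs_a = {tuple(f.held_out_pair): f.metrics[metric] for f in a.folds}
    pairs_b = {tuple(f.held_out_pair): f.metrics[metric] for f in b.folds}
    if set(pairs_a) != set(pairs_b):
        raise ProtocolError("runs hold out different subject pairs; cannot pair folds")
    keys = sorted(pairs_a)
    return paired_one_sided_t_test([pairs_a[k] for k in keys], [pairs_b[k] for k in keys])


# -- data plumbing ---------------------------------------------------------------

def prepare_windows(
    recordings: list[EEGRecording],
    segment_seconds: float = 180.0,
    window_seconds: float = 2.0,
    preprocess: bool = True,
    band: tuple[float, float] = (0.5, 70.0),
    notch: float | None = 50.0,
) -> list[WindowSample]:
    """Filter, cut the centered segment, and window every recording."""
    windows: list[WindowSample] = []
    for rec in recordings:
        if preprocess:
            rec = bandpass_notch(rec, band[0], band[1], notch)
        rec = extract_middle_segment(rec, segment_seconds)
        windows.extend(make_windows(rec, window_seconds))
    return windows


def windows_to_arrays(
    windows: list[WindowSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X, y, subject_ids); MDD is class 1."""
    x = np.stack([w.x for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows], dtype=np.int64)
    subjects = np.array([w.subject_id for w in windows])
    return x, y, subjects


# -- training -------------------------------------------------------------------

def _batched_eval(model: HemiGraphNet, x: np.ndarray, y: np.ndarray,
                  batch_size: int) -> tuple[float, float]:
    """(mean loss, accuracy fraction) in eval mode without the tape."""
    model.eval()
    losses, correct = [], 0
    with no_grad():
        for i in range(0, len(x), batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            scores = model.forward(xb)
            losses.append(T.cross_entropy_with_logits(scores, yb).data * len(yb))
            correct += int((np.argmax(scores.data, axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_fold(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    held_out_pair: tuple[str, str],
    model_config: ModelConfig,
    train_config: TrainConfig,
    fold_seed: int = 0,
    train_subjects: np.ndarray | None = None,
) -> tuple[FoldResult, HemiGraphNet]:
    """Train on one fold's pool and evaluate once on the held-out pair.

    Optimizes window-level cross-entropy; keeps the checkpoint with the best
    validation accuracy (ties broken by lower validation loss); stops early
    when the validation loss has not improved for ``early_stop_patience``
    epochs.
    """
    if len(train_x) == 0 or len(test_x) == 0:
        raise ProtocolError("fold has empty train or test set")
    ss = np.random.SeedSequence(fold_seed)
    model_seed, split_seed, batch_seed = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(3))
    tr_idx, val_idx = split_train_val(
        train_y,
        train_config.val_fraction,
        split_seed,
        subjects=train_subjects,
        level=train_config.val_split,
    )
    x_tr, y_tr = train_x[tr_idx], train_y[tr_idx]
    x_val, y_val = train_x[val_idx], train_y[val_idx]

    model = HemiGraphNet(model_config, seed=model_seed)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    scheduler = CosineAnnealingLR(optimizer, train_config.t_max, train_config.eta_min)
    batch_rng = np.random.default_rng(batch_seed)

    best_state = model.state_dict()
    best_acc, best_loss, best_epoch = -1.0, np.inf, 0
    es_best_loss, es_counter = np.inf, 0
    epochs_run = 0

    for epoch in range(1, train_config.max_epochs + 1):
        epochs_run = epoch
        model.train()
        order = batch_rng.permutation(len(x_tr))
        for i in range(0, len(order), train_config.batch_size):
            idx = order[i : i + train_config.batch_size]
            scores = model.forward(x_tr[idx])
            loss = T.cross_entropy_with_logits(scores, y_tr[idx])
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        scheduler.step()

        val_loss, val_acc = _batched_eval(model, x_val, y_val, train_config.batch_size)
        logger.info(
            "pair=%s epoch=%d lr=%.2e val_loss=%.4f val_acc=%.4f",
            "/".join(held_out_pair), epoch, optimizer.lr, val_loss, val_acc,
        )
        if val_acc > best_acc or (val_acc == best_acc and val_loss < best_loss):
            best_acc, best_loss, best_epoch = val_acc, val_loss, epoch
            best_state = model.state_dict()
        if val_loss < es_best_loss - 1e-12:
            es_best_loss, es_counter = val_loss, 0
        else:
            es_counter += 1
            if es_counter >= train_config.early_stop_patience:
                break

    model.load_state_dict(best_state)
    pred = model.predict(test_x, batch_size=train_config.batch_size)
    tp = int(((pred == 1) & (test_y == 1)).sum())
    tn = int(((pred == 0) & (test_y == 0)).sum())
    fp = int(((pred == 1) & (test_y == 0)).sum())
    fn = int(((pred == 0) & (test_y == 1)).sum())
    result = FoldResult(
        held_out_pair=held_out_pair,
        confusion=dict(tp=tp, tn=tn, fp=fp, fn=fn),
        metrics=compute_metrics(tp, tn, fp, fn),
        best_epoch=best_epoch,
        epochs_run=epochs_run,
    )
    return result, model


# -- full experiment -------------------------------------------------------------

def run_experiment(
    cohort: list[EEGRecording] | str | Path,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    segment_seconds: float = 180.0,
    window_seconds: float = 2.0,
    preprocess: bool = True,
) -> EvalSummary:
    """Full leave-one-pair-out sweep over a cohort (recordings or manifest path)."""
    recordings = cohort if isinstance(cohort, list) else load_cohort(cohort)
    windows = prepare_windows(
        recordings, segment_seconds, window_seconds, preprocess=preprocess
    )
    x, y, subjects = windows_to_arrays(windows)
    groups = {w.subject_id: w.group for w in windows}
    ss = np.random.SeedSequence(train_config.seed)
    pair_seed, *fold_seeds = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(
        1 + len({s for s in subjects if groups[s] == "MDD"})
    ))
    pairs = make_lopo_folds(sorted(groups.items()), seed=pair_seed)

    folds: list[FoldResult] = []
    for (mdd_id, hc_id), fold_seed in zip(pairs, fold_seeds):
        test_mask = (subjects == mdd_id) | (subjects == hc_id)
        assert not (
            set(subjects[~test_mask]) & {mdd_id, hc_id}
        ), "held-out subjects leaked into the training pool"
        result, _ = train_fold(
            x[~test_mask],
            y[~test_mask],
            x[test_mask],
            y[test_mask],
            (mdd_id, hc_id),
            model_config,
            train_config,
            fold_seed=fold_seed,
            train_subjects=subjects[~test_mask],
        )
        folds.append(result)

    agg = {
        key: int(sum(f.confusion[key] for f in folds)) for key in ("tp", "tn", "fp", "fn")
    }
    per_metric = {
        m: np.array([f.metrics[m] for f in folds], dtype=np.float64)
        for m in METRIC_NAMES
    }
    mean = {m: float(np.nanmean(v)) for m, v in per_metric.items()}
    std = {
        m: float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0
        for m, v in per_metric.items()
    }
    return EvalSummary(
        folds=folds,
        mean=mean,
        std=std,
        aggregated_confusion=agg,
        pooled_metrics=compute_metrics(**agg),
        model_config=model_config.to_dict(),
        train_config=train_config.to_dict(),
    )
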