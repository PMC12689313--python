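"""Training loop, classification metrics, patient-level bootstrap CIs,
majority voting, SNR-controlled noise mixing and patient-level
cross-validation.

Metrics follow the standard confusion-matrix formulas (accuracy,
sensitivity, specificity, PPV, F1 = harmonic mean of PPV and sensitivity),
reported as percentages.  Confidence intervals resample patients (not
segments) with replacement; cross-validation partitions patients into k
folds and pairs of model variants are compared with the two-sided Wilcoxon
signed-rank test on per-fold scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .audioprep import make_cv_folds
from .nn import AdamW, cross_entropy
from .nn.autograd import Tensor

__all__ = [
    "TrainConfig", "ConfusionCounts", "MetricReport", "SNRMixSpec",
    "compute_metrics", "bootstrap_ci", "majority_vote", "mix_at_snr",
    "train", "predict", "crossval_5fold", "compare_variants",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    lr: float = 2e-4
    weight_decay: float = 0.05
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.lr < 0 or self.weight_decay < 0:
            raise ValueError("invalid training configuration")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("empty confusion table")

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return ConfusionCounts(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()))


@dataclass
class MetricReport:
    """Percentages; a metric whose denominator is empty is None (flagged
    undefined, never silently zero)."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    f1: float | None
    ci_low: float | None = None
    ci_high: float | None = None


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    total = c.TP + c.TN + c.FP + c.FN
    acc = 100.0 * (c.TP + c.TN) / total
    sens = 100.0 * c.TP / (c.TP + c.FN) if c.TP + c.FN else None
    spec = 100.0 * c.TN / (c.TN + c.FP) if c.TN + c.FP else None
    ppv = 100.0 * c.TP / (c.TP + c.FP) if c.TP + c.FP else None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    elif ppv == 0 and sens == 0:
        f1 = 0.0
    else:
        f1 = None
    return MetricReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        ppv=ppv, f1=f1)


def bootstrap_ci(per_patient_accuracy: dict, B: int = 1000, seed: int = 42):
    """95% CI for the patient-mean accuracy by resampling patients with
    replacement.  ``per_patient_accuracy`` maps patient id -> accuracy (%)."""
    vals = np.asarray(list(per_patient_accuracy.values()), dtype=float)
    if len(vals) < 2:
        raise ValueError("bootstrap needs at least 2 patients")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(B, len(vals)))
    means = vals[idx].mean(axis=1)
    return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))


def majority_vote(per_segment_predictions: dict) -> dict:
    """Patient label = modal segment prediction; an exact tie resolves to
    the positive class."""
    out = {}
    for pid, preds in per_segment_predictions.items():
        preds = np.asarray(preds)
        pos = int((preds == 1).sum())
        out[pid] = 1 if pos * 2 >= len(preds) else 0
    return out


@dataclass(frozen=True)
class SNRMixSpec:
    snr_db: float
    seed: int = 0


def mix_at_snr(signal: np.ndarray, noise: np.ndarray, snr_db: float,
               seed: int = 0) -> np.ndarray:
    """Additively mix noise into signal at an exact target SNR.

    The noise is looped from a seeded random phase offset (or cropped) to
    the signal length, then scaled so 10*log10(P_signal / P_noise) equals
    ``snr_db``."""
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    p_sig = np.mean(signal**2)
    if p_sig <= 0:
        raise ValueError("SNR undefined for a silent signal")
    if not np.any(noise):
        raise ValueError("SNR undefined for silent noise")
    n = len(signal)
    if len(noise) < n:
        rng = np.random.default_rng(seed)
        offset = int(rng.integers(0, len(noise)))
        reps = -(-((n + offset)) // len(noise))
        noise = np.tile(noise, reps + 1)[offset:offset + n]
    else:
        noise = noise[:n]
    p_noise = np.mean(noise**2)
    scale = np.sqrt(p_sig / (p_noise * 10.0 ** (snr_db / 10.0)))
    return signal + scale * noise


# ---------------------------------------------------------------- training
def train(model, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
          X_val: np.ndarray | None = None, y_val: np.ndarray | None = None):
    """Mini-batch AdamW training with cross-entropy loss.

    ``X`` is (N, 3, H, W); returns a history dict with per-epoch train loss
    (and validation loss/accuracy when a validation set is given).
    Deterministic given cfg.seed and the data order.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = cross_entropy(model(Tensor(X[idx])), y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
        history["train_loss"].append(sum(losses) / len(X))
        if X_val is not None:
            logits = _forward_batched(model, X_val, cfg.batch_size)
            history["val_loss"].append(
                float(cross_entropy(Tensor(logits), y_val).data))
            history["val_accuracy"].append(
                float((logits.argmax(axis=1) == y_val).mean()))
    return history


def _forward_batched(model, X, batch_size):
    outs = []
    for start in range(0, len(X), batch_size):
        outs.append(model(Tensor(X[start:start + batch_size])).data)
    return np.concatenate(outs, axis=0)


def predict(model, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    return _forward_batched(model, X, batch_size).argmax(axis=1)


# ---------------------------------------------------------- cross-validation
def crossval_5fold(records, fit_predict_fn, k: int = 5, seed: int = 0):
    """Patient-level k-fold cross-validation.

    ``fit_predict_fn(train_records, val_records) -> (y_true, y_pred)`` is
    called once per fold; returns (per-fold MetricReports, mean, SD) of
    accuracy."""
    folds = make_cv_folds(records, k=k, seed=seed)
    reports = []
    for i in range(k):
        val = folds[i]
        trn = [r for j in range(k) if j != i for r in folds[j]]
        y_true, y_pred = fit_predict_fn(trn, val)
        reports.append(compute_metrics(
            ConfusionCounts.from_predictions(y_true, y_pred)))
    accs = np.array([r.accuracy for r in reports])
    return reports, float(accs.mean()), float(accs.std(ddof=1))


def compare_variants(scores_a, scores_b):
    """Two-sided Wilcoxon signed-rank test on paired per-fold scores.

    Zero differences are dropped (the classical convention); if every pair
    is tied the test cannot reject and (statistic None, p 1.0) is returned.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    if np.all(a == b):
        return None, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox",
                         method="auto")
    return float(res.statistic), float(res.pvalue)
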