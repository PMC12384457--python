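"""Metrics and evaluation protocols for motor-imagery decoding.

Accuracy is the trace of the confusion matrix over its total; Cohen's kappa
is the chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e) with
p_o the observed agreement and p_e the agreement expected from the
marginals.  Paired model comparisons use the Wilcoxon signed-rank test
(exact null for small n, zero differences dropped, two-sided).

Two protocols are orchestrated: subject-dependent (session-based split per
subject) and leave-one-subject-out (LOSO).  Both z-score each training
partition on its own statistics and apply them to the test partition, train
a fresh model per subject/fold, and report per-subject accuracy and kappa
plus their means and the summed confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import TrialSet, loso_folds, subject_dependent_split, zscore_channels
from .model import ModelConfig, TrainConfig, build_model, predict_labels, train_model
from .montage import SpatialGraph

__all__ = [
    "EvalResult",
    "confusion_matrix",
    "accuracy",
    "cohen_kappa",
    "wilcoxon_signed_rank",
    "significance_stars",
    "run_protocol",
]


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """Counts matrix with entry (i, j) = true class i predicted as j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def accuracy(confusion: np.ndarray) -> float:
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def cohen_kappa(confusion: np.ndarray) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) from a counts matrix."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(confusion) / total
    p_e = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum() / total**2)
    if p_e >= 1.0:
        warnings.warn(
            "degenerate confusion matrix (expected agreement 1); kappa set to 0",
            stacklevel=2,
        )
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def wilcoxon_signed_rank(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped (Wilcoxon's original method); the exact
    null distribution is used for n <= 25, a normal approximation with
    continuity correction above.  Requires n >= 5 non-zero differences.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    diff = a - b
    n = int((diff != 0).sum())
    if n == 0:
        raise ValueError("all paired differences are zero: no information")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method,
        **({"correction": True} if method == "approx" else {}),
    )
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class EvalResult:
    protocol: str
    subject_ids: list[int]
    accuracies: list[float]
    kappas: list[float]
    confusion: np.ndarray
    histories: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.kappas))

    def to_frame(self) -> pd.DataFrame:
        """Per-subject rows plus a final Mean row."""
        rows = [
            {"subject": s, "protocol": self.protocol,
             "accuracy": a, "kappa": k}
            for s, a, k in zip(self.subject_ids, self.accuracies, self.kappas)
        ]
        rows.append(
            {"subject": "Mean", "protocol": self.protocol,
             "accuracy": self.mean_accuracy, "kappa": self.mean_kappa}
        )
        return pd.DataFrame(rows)


def _fit_and_score(
    cfg: ModelConfig, graph: SpatialGraph, tcfg: TrainConfig,
    train: TrialSet, test: TrialSet,
) -> tuple[float, float, np.ndarray, object]:
    train_z = zscore_channels(train)
    test_z = zscore_channels(test, stats_from=train)
    model = build_model(cfg, graph, seed=tcfg.seed)
    model, hist = train_model(model, train_z, tcfg)
    pred = predict_labels(model, test_z.data, tcfg.batch_size)
    cm = confusion_matrix(test_z.labels, pred, cfg.n_classes)
    return accuracy(cm), cohen_kappa(cm), cm, hist


def run_protocol(
    cfg: ModelConfig,
    tcfg: TrainConfig,
    data: TrialSet,
    protocol: str,
    graph: SpatialGraph,
    session_scheme: str = "2a",
    out_csv: str | Path | None = None,
) -> EvalResult:
    """Run the subject-dependent or LOSO protocol over a multi-subject set."""
    if protocol not in {"dependent", "loso"}:
        raise ValueError(f"unknown protocol {protocol!r}; choose dependent or loso")
    subject_ids: list[int] = []
    accs: list[float] = []
    kappas: list[float] = []
    hists: list = []
    confusion = np.zeros((cfg.n_classes, cfg.n_classes), dtype=np.int64)
    if protocol == "dependent":
        for sid in np.unique(data.subjects):
            per = data.select(np.flatnonzero(data.subjects == sid))
            train, test = subject_dependent_split(per, session_scheme)
            assert not np.isin(train.sessions, np.unique(test.sessions)).any()
            acc, kap, cm, hist = _fit_and_score(cfg, graph, tcfg, train, test)
            subject_ids.append(int(sid))
            accs.append(acc)
            kappas.append(kap)
            hists.append(hist)
            confusion += cm
    else:
        for train, test in loso_folds(data):
            sid = int(test.subjects[0])
            assert sid not in set(train.subjects)  # leakage guard
            acc, kap, cm, hist = _fit_and_score(cfg, graph, tcfg, train, test)
            subject_ids.append(sid)
            accs.append(acc)
            kappas.append(kap)
            hists.append(hist)
            confusion += cm
    result = EvalResult(
        protocol=protocol, subject_ids=subject_ids, accuracies=accs,
        kappas=kappas, confusion=confusion, histories=hists,
    )
    if out_csv is not None:
        result.to_frame().to_csv(out_csv, index=False)
    return result
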