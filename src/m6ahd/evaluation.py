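"""Classifier evaluation: confusion metrics, ranking metrics and
cross-condition prediction matrices.

Threshold metrics follow the usual definitions
Sn = TP/(TP+FN), Sp = TN/(FP+TN), ACC = (TP+TN)/(TP+FP+TN+FN),
with a positive call whenever score >= threshold (default 0.5; ties count
as positive). AUROC is the rank (Mann-Whitney) statistic with ties counted
one half; AUPRC is step-interpolated average precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

__all__ = [
    "EvalResult",
    "CrossPredictionMatrix",
    "confusion",
    "auroc",
    "auprc",
    "evaluate_scores",
    "roc_points",
    "pr_points",
    "cross_predict",
]


@dataclass
class EvalResult:
    """Confusion counts plus summary metrics for one model on one test set."""

    TP: int
    FP: int
    TN: int
    FN: int
    threshold: float
    Sn: float
    Sp: float
    ACC: float
    AUROC: float
    AUPRC: float

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "threshold": self.threshold, "Sn": self.Sn, "Sp": self.Sp,
            "ACC": self.ACC, "AUROC": self.AUROC, "AUPRC": self.AUPRC,
        }


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5):
    """Confusion counts with positive calls at score >= threshold."""
    scores, labels = _check(scores, labels)
    calls = scores >= threshold
    TP = int(np.sum(calls & (labels == 1)))
    FP = int(np.sum(calls & (labels == 0)))
    TN = int(np.sum(~calls & (labels == 0)))
    FN = int(np.sum(~calls & (labels == 1)))
    return TP, FP, TN, FN


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic, ties counted 1/2)."""
    scores, labels = _check(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average precision)."""
    scores, labels = _check(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, scores))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalResult:
    """Full evaluation; Sn/Sp are NaN (with a warning) when their
    denominator class is absent."""
    TP, FP, TN, FN = confusion(scores, labels, threshold)
    if TP + FN == 0:
        warnings.warn("no positives in test set; Sn undefined")
        Sn = float("nan")
    else:
        Sn = TP / (TP + FN)
    if FP + TN == 0:
        warnings.warn("no negatives in test set; Sp undefined")
        Sp = float("nan")
    else:
        Sp = TN / (FP + TN)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    labels_arr = np.asarray(labels, dtype=int)
    both = 0 < labels_arr.sum() < labels_arr.size
    return EvalResult(
        TP, FP, TN, FN, threshold, Sn, Sp, ACC,
        AUROC=auroc(scores, labels) if both else float("nan"),
        AUPRC=auprc(scores, labels) if labels_arr.sum() > 0 else float("nan"),
    )


def roc_points(scores, labels) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_points(scores, labels) -> pd.DataFrame:
    prec, rec, thr = precision_recall_curve(labels, scores)
    return pd.DataFrame(
        {"precision": prec, "recall": rec,
         "threshold": np.append(thr, np.nan)}
    )


# ---------------------------------------------------------------------------
# Cross-condition prediction
# ---------------------------------------------------------------------------

@dataclass
class CrossPredictionMatrix:
    """AUROC of each source-condition model applied to each target
    condition's test set, for one direction (up or down)."""

    direction: str
    table: pd.DataFrame  # rows: source model condition; cols: target condition
    missing: dict = field(default_factory=dict)  # (source, target) -> reason

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def _trim_center(seq: str, L: int) -> str:
    excess = len(seq) - L
    if excess < 0:
        raise ValueError("window shorter than requested length")
    if excess % 2:
        raise ValueError("asymmetric trim; window lengths must share parity")
    k = excess // 2
    return seq[k : k + L] if k else seq


def cross_predict(models: dict, datasets: dict, direction: str) -> CrossPredictionMatrix:
    """Score every source model on every target condition's windows.

    Target windows are trimmed centrally to the source model's window
    length and encoded with the source model's encoder spec. A target whose
    windows are shorter than a source length yields a missing cell with a
    recorded reason.
    """
    from .encoders import SequenceWindow, build_feature_matrix
    from .pipeline import predict

    conditions_src = list(models)
    conditions_tgt = list(datasets)
    table = pd.DataFrame(
        np.nan, index=conditions_src, columns=conditions_tgt, dtype=float
    )
    missing = {}
    for src in conditions_src:
        model = models[src]
        L = model.config.window_length
        for tgt in conditions_tgt:
            pairs = datasets[tgt]
            if not pairs:
                missing[(src, tgt)] = "empty target dataset"
                continue
            if len(pairs[0][0]) < L:
                missing[(src, tgt)] = (
                    f"target windows ({len(pairs[0][0])} nt) shorter than "
                    f"source window length ({L} nt)"
                )
                continue
            windows = [
                SequenceWindow(_trim_center(w.seq, L), site_ref=w.site_ref,
                               center_check=w.center_check)
                for w, _ in pairs
            ]
            labels = np.array([lab for _, lab in pairs])
            fm = build_feature_matrix(windows, model.config.encoder_spec, labels)
            scores = predict(model, fm)
            table.loc[src, tgt] = auroc(scores, labels)
    return CrossPredictionMatrix(direction=direction, table=table, missing=missing)
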