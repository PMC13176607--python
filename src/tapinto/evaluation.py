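"""Benchmark harness: PPV/NPV at the subgroup cutoff, ROC/AUC, mean-FC baseline.

The subgroup call is treated as a binary classifier over labeled samples
(e.g. IHC-positive vs -negative): predicted positives are the subgroup
members, and PPV = TP/(TP+FP), NPV = TN/(TN+FN).  Gene-level scores (e.g.
subgroup fold changes) are compared against a labeled antigen list with a
rank-based AUC (ties counted 1/2, i.e. the Mann–Whitney convention, which
coincides with the trapezoidal ROC area).  The whole-population baseline FC
is mean(tumor)/mean(normal), the quantity a t-test-style method would rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .dataset import ExpressionDataset
from .errors import InputError, RoleConfigError
from .outliers import OutlierCall

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_label_series(labels: Mapping[str, str] | pd.Series) -> pd.Series:
    s = labels if isinstance(labels, pd.Series) else pd.Series(dict(labels))
    bad = set(s.unique()) - {POSITIVE, NEGATIVE}
    if bad:
        raise InputError(f"labels must be positive/negative, got {sorted(bad)!r}")
    return s.astype(str)


def confusion_at_cutoff(
    call: OutlierCall,
    labels: Mapping[str, str] | pd.Series,
    cohort: Sequence[str] | None = None,
) -> ConfusionCounts:
    """Confusion counts of the subgroup call against binary sample labels.

    ``cohort`` defaults to the labeled sample IDs; every cohort sample must
    carry a label.  Predicted positive = subgroup membership.
    """
    s = _as_label_series(labels)
    ids = list(s.index) if cohort is None else list(cohort)
    missing = [i for i in ids if i not in s.index]
    if missing:
        raise InputError(f"unlabeled samples in cohort: {missing[:5]}")
    members = set(call.members)
    tp = fp = tn = fn = 0
    for i in ids:
        predicted_pos = i in members
        actual_pos = s[i] == POSITIVE
        if predicted_pos and actual_pos:
            tp += 1
        elif predicted_pos:
            fp += 1
        elif actual_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def ppv_npv(counts: ConfusionCounts) -> tuple[float, float]:
    """(PPV, NPV) = (TP/(TP+FP), TN/(TN+FN)); NaN on an empty denominator."""
    pp = counts.tp + counts.fp
    pn = counts.tn + counts.fn
    ppv = counts.tp / pp if pp else float("nan")
    npv = counts.tn / pn if pn else float("nan")
    return ppv, npv


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Rank-formula AUC plus the ROC point set.

    AUC = P(score_pos > score_neg) + 0.5 · P(tie), computed from mid-ranks
    (Mann–Whitney identity); invariant under strictly increasing score
    transforms.  ROC points are enumerated at every distinct threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(
        [1 if l == POSITIVE else 0 for l in np.asarray(labels, dtype=object)]
    )
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC needs both a positive and a negative class")
    ranks = rankdata(scores, method="average")
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc), points


def baseline_mean_fc(ds: ExpressionDataset) -> pd.Series:
    """Whole-population fold change mean(tumor)/mean(normal) per gene.

    The mean-based baseline a t-test pipeline would rank; NaN where the
    normal mean is zero (same policy as the subgroup FC).
    """
    if ds.n_normal == 0:
        raise RoleConfigError("mean-FC baseline requires normal samples")
    t = ds.values[ds.tumor_ids].mean(axis=1)
    n = ds.values[ds.normal_ids].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = t / n
    fc[n == 0] = np.nan
    fc.name = "mean_fc"
    return fc
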