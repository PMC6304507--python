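"""Fluid-marker cutoff diagnostics: confusion-matrix rates at a fixed
concentration cutoff and ROC AUC, as used for cyst-fluid CEA (mucinous vs
nonmucinous, 192 ng/mL) and amylase (duct-communicating vs not, 250 IU/L).

A sample is test-positive when its marker value is greater than or equal to
the cutoff. AUC is the probability that a random positive outranks a random
negative, with ties counted half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

CEA_CUTOFF_NG_ML = 192.0
AMYLASE_CUTOFF_IU_L = 250.0
MUCINOUS_GROUPS = ("IPMN", "MCN")
AMYLASE_RICH_GROUPS = ("PC", "IPMN")


@dataclass
class CutoffReport:
    cutoff: float
    n_pos: int
    n_neg: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _clean(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    keep = ~np.isnan(v)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d samples with missing marker values", dropped)
    return v[keep], y[keep]


def evaluate_cutoff(values, labels, cutoff: float) -> CutoffReport:
    """Confusion-matrix report for 'value >= cutoff' as the positive call.

    ``labels`` is the binary reference class (True = diseased/positive).
    Missing marker values are excluded with a logged count.
    """
    v, y = _clean(values, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative sample")
    pred = v >= cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    return CutoffReport(
        cutoff=float(cutoff), n_pos=n_pos, n_neg=n_neg, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / n_pos, specificity=tn / n_neg,
        accuracy=(tp + tn) / (n_pos + n_neg), auc=roc_auc(v, y),
    )


def roc_auc(values, labels, method: str = "pairwise") -> float:
    """ROC area: P(value_pos > value_neg) + 0.5 P(tie).

    Two independent routes are provided: "pairwise" (rank / Mann-Whitney
    form) and "trapezoid" (explicit ROC-curve integration); they agree to
    floating-point precision.
    """
    v, y = _clean(values, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative sample")
    if method == "pairwise":
        ranks = rankdata(v)  # average ranks implement the half-tie rule
        return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    if method == "trapezoid":
        order = np.argsort(-v, kind="stable")
        vs, ys = v[order], y[order]
        tps = np.cumsum(ys)
        fps = np.cumsum(~ys)
        # one ROC vertex per distinct threshold (include the origin)
        last = np.r_[np.diff(vs) != 0, True]
        tpr = np.r_[0.0, tps[last] / n_pos]
        fpr = np.r_[0.0, fps[last] / n_neg]
        return float(np.trapezoid(tpr, fpr))
    raise ValueError(f"unknown method {method!r}")


def roc_points(values, labels) -> pd.DataFrame:
    """The ROC curve vertices (threshold, fpr, tpr) for plotting/export."""
    v, y = _clean(values, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    order = np.argsort(-v, kind="stable")
    vs, ys = v[order], y[order]
    last = np.r_[np.diff(vs) != 0, True]
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, vs[last]],
            "fpr": np.r_[0.0, np.cumsum(~ys)[last] / n_neg],
            "tpr": np.r_[0.0, np.cumsum(ys)[last] / n_pos],
        }
    )


def marker_report(
    samples: pd.DataFrame,
    marker: str,
    positive_groups: tuple[str, ...],
    cutoff: float,
    exclude_groups: tuple[str, ...] = ("UNC",),
) -> CutoffReport:
    """Cutoff diagnostics for one marker column of the sample table, with
    the positive class defined by cyst-type membership."""
    use = samples[~samples["group"].isin(exclude_groups)]
    labels = use["group"].isin(positive_groups).to_numpy()
    return evaluate_cutoff(use[marker].to_numpy(float), labels, cutoff)
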