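"""Log transformation and LOESS normalization against a median pseudosample.

Each sample is regressed against the per-feature median profile
("pseudosample") on a set of low-variance anchor features; the fitted
robust-LOESS correction curve is then applied to every feature of that
sample. This removes intensity-dependent systematic bias (ionization,
loading) while leaving biological structure intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import QuantMatrix


def log_transform(m: QuantMatrix) -> QuantMatrix:
    """log2-transform a linear-scale matrix. Zero or negative present values
    are an error — there is no silent pseudocount."""
    if m.scale != "linear":
        raise ValueError("log_transform expects a linear-scale matrix")
    vals = m.data.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive abundance at feature {m.feature_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}; cannot log-transform"
        )
    return QuantMatrix(np.log2(m.data), scale="log2")


def median_pseudosample(m: QuantMatrix, max_missing_frac: float = 0.5) -> pd.Series:
    """Per-feature median of log2 abundances across samples (NaN-ignoring).

    Features missing in more than ``max_missing_frac`` of samples get NaN and
    are thereby excluded from curve fitting, though they remain correctable.
    """
    med = m.data.median(axis=1, skipna=True)
    frac_missing = m.data.isna().mean(axis=1)
    med[frac_missing > max_missing_frac] = np.nan
    return med


def select_anchors(
    m: QuantMatrix, fraction: float = 0.25, min_present: int | None = None
) -> list[str]:
    """The ``ceil(fraction * n_eligible)`` features with smallest
    across-sample variance, among features with at least ``min_present``
    non-missing values. Ties break lexicographically on feature_id."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n_samples = len(m.sample_ids)
    if n_samples < 2:
        raise ValueError("anchor selection needs at least 2 samples")
    if min_present is None:
        min_present = math.ceil(0.8 * n_samples)
    present = m.data.notna().sum(axis=1)
    eligible = m.data.loc[present >= max(2, min_present)]
    if eligible.empty:
        raise ValueError(
            f"no features with >= {min_present} present values; "
            "lower min_present or check the matrix"
        )
    variances = eligible.var(axis=1, ddof=1, skipna=True)
    order = sorted(variances.index, key=lambda f: (variances[f], f))
    k = math.ceil(fraction * len(order))
    return order[:k]


@dataclass
class NormalizationModel:
    """Fitted normalization state: the pseudosample, the anchors, and one
    correction curve per sample, stored as interpolation knots."""

    pseudosample: pd.Series
    anchor_ids: list[str]
    span: float
    curves: dict[str, tuple[np.ndarray, np.ndarray]]

    def correction(self, sample_id: str, x: np.ndarray) -> np.ndarray:
        """Evaluate the sample's correction curve at abundance x (constant
        extension beyond the fitted range)."""
        xs, ys = self.curves[sample_id]
        return np.interp(x, xs, ys)


class LoessNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn-style transformer for pseudosample LOESS normalization.

    Operates on samples x features arrays/DataFrames of log2 abundances with
    NaN for missing values. ``fit`` establishes the pseudosample and anchor
    set on the training cohort; ``transform`` fits a robust LOESS of
    (sample - pseudosample) against the pseudosample on anchors and subtracts
    the fitted curve from every feature of that sample.

    Parameters
    ----------
    anchor_fraction : fraction of eligible features used as anchors.
    span : LOESS bandwidth fraction in (0, 1].
    min_present : minimum non-missing values for anchor eligibility
        (default: 80% of fitted samples).
    robust_iter : robustifying (bisquare) iterations.
    """

    def __init__(
        self,
        anchor_fraction: float = 0.25,
        span: float = 0.3,
        min_present: int | None = None,
        robust_iter: int = 3,
        max_missing_frac: float = 0.5,
    ):
        self.anchor_fraction = anchor_fraction
        self.span = span
        self.min_present = min_present
        self.robust_iter = robust_iter
        self.max_missing_frac = max_missing_frac

    def fit(self, X, y=None):
        df = pd.DataFrame(X)
        self.feature_names_ = df.columns.to_numpy()
        qm = QuantMatrix(df.T, scale="log2")
        self.pseudosample_ = median_pseudosample(qm, self.max_missing_frac)
        self.anchor_ids_ = select_anchors(qm, self.anchor_fraction, self.min_present)
        return self

    def transform(self, X):
        df = pd.DataFrame(X)
        qm = QuantMatrix(df.T, scale="log2")
        out, _ = _apply_loess(
            qm, self.pseudosample_, self.anchor_ids_, self.span, self.robust_iter
        )
        return out.data.T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def _apply_loess(
    m: QuantMatrix,
    pseudo: pd.Series,
    anchor_ids: list[str],
    span: float,
    robust_iter: int,
) -> tuple[QuantMatrix, NormalizationModel]:
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")
    pseudo = pseudo.reindex(m.data.index)
    # evaluation abscissa: the pseudosample value of each feature; features
    # excluded from the pseudosample still get an x from their own median
    x_all = pseudo.fillna(m.data.median(axis=1, skipna=True)).to_numpy()

    corrected = m.data.copy()
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sample in m.sample_ids:
        col = m.data[sample]
        mask = pseudo.notna() & col.notna() & pseudo.index.isin(anchor_ids)
        x = pseudo[mask].to_numpy()
        y = (col[mask] - pseudo[mask]).to_numpy()
        if len(x) < max(3, math.ceil(span * len(x))) or len(x) < 3:
            raise ValueError(
                f"sample {sample!r}: only {len(x)} anchor points available; "
                "increase the anchor fraction or the span"
            )
        fit = lowess(y, x, frac=span, it=robust_iter, return_sorted=True)
        xs, ys = fit[:, 0], fit[:, 1]
        # collapse duplicate abscissae so np.interp is well defined
        if len(np.unique(xs)) != len(xs):
            ser = pd.Series(ys).groupby(pd.Series(xs)).mean()
            xs, ys = ser.index.to_numpy(), ser.to_numpy()
        curves[sample] = (xs, ys)
        corrected[sample] = col.to_numpy() - np.interp(x_all, xs, ys)

    model = NormalizationModel(pseudo, list(anchor_ids), span, curves)
    out = QuantMatrix(corrected, scale="log2")
    # normalization must never create or destroy missingness
    assert out.data.isna().equals(m.data.isna())
    return out, model


def normalize_loess(
    m: QuantMatrix,
    fraction: float = 0.25,
    span: float = 0.3,
    min_present: int | None = None,
    robust_iter: int = 3,
    max_missing_frac: float = 0.5,
) -> tuple[QuantMatrix, NormalizationModel]:
    """Normalize a log2 matrix against its median pseudosample (see
    :class:`LoessNormalizer`); returns the corrected matrix and the model."""
    if m.scale != "log2":
        raise ValueError("normalize_loess expects a log2-scale matrix")
    if len(m.sample_ids) < 2:
        raise ValueError("normalization needs at least 2 samples")
    pseudo = median_pseudosample(m, max_missing_frac)
    anchors = select_anchors(m, fraction, min_present)
    return _apply_loess(m, pseudo, anchors, span, robust_iter)
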