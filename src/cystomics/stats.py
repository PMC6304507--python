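"""Resampling-based ANOVA for differential abundance across cyst types.

Per feature, a one-way F-statistic is computed on the present (non-missing)
values and its null distribution is built by permuting group labels over
those same samples — the missingness pattern is preserved under the null.
When the number of distinct label assignments is small enough the null is
enumerated exhaustively and the p-value is exact; otherwise Monte-Carlo
sampling with the (1 + B)/(1 + n_perm) correction guarantees a valid test.
P-values are adjusted by the Benjamini–Hochberg step-up, and features are
called significant when the adjusted p is at most ``alpha`` AND the maximal
pairwise linear fold change between group means is at least ``fc_min``.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import QuantMatrix

_EPS = 1e-9  # absolute slack when comparing permuted F against observed F


# ---------------------------------------------------------------------------
# F statistic
# ---------------------------------------------------------------------------

def _f_stat(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """One-way ANOVA F on complete data (codes in 0..k-1)."""
    n = len(values)
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    if sst <= 0:
        return 0.0
    ssb = 0.0
    for g in range(k):
        vg = values[codes == g]
        ssb += len(vg) * (vg.mean() - grand) ** 2
    ssw = sst - ssb
    if ssw <= 0:
        return np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def _n_assignments(counts: list[int]) -> int:
    n = sum(counts)
    total = factorial(n)
    for c in counts:
        total //= factorial(c)
    return total


def _enumerate_assignments(n: int, counts: list[int]):
    """Yield all distinct assignments of n items into groups of the given
    sizes, as code arrays."""
    def rec(remaining: tuple[int, ...], g: int, codes: np.ndarray):
        if g == len(counts) - 1:
            for i in remaining:
                codes[i] = g
            yield codes.copy()
            return
        for chosen in combinations(remaining, counts[g]):
            for i in chosen:
                codes[i] = g
            rest = tuple(i for i in remaining if i not in set(chosen))
            yield from rec(rest, g + 1, codes)
    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def perm_anova(
    values: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    exhaustive_limit: int = 20000,
    min_per_group: int = 2,
) -> tuple[float, float]:
    """Permutation ANOVA for one feature.

    ``values`` may contain NaN (missing measurements); groups with fewer
    than ``min_per_group`` present values are dropped from the test. Returns
    ``(F, p)``; raises ValueError if fewer than two groups remain testable.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    present = ~np.isnan(values)
    v, g = values[present], groups[present]

    labels = [lab for lab in pd.unique(g) if (g == lab).sum() >= min_per_group]
    if len(labels) < 2:
        raise ValueError("needs >= 2 groups with enough present values")
    keep = np.isin(g, labels)
    v, g = v[keep], g[keep]

    # order samples by group so permuted group membership is a column block
    order = np.argsort(pd.Categorical(g, categories=labels).codes, kind="stable")
    v = v[order]
    codes = np.sort(pd.Categorical(g, categories=labels).codes)
    k = len(labels)
    counts = [int((codes == i).sum()) for i in range(k)]
    n = len(v)

    if np.ptp(v) == 0:  # no variance at all: degenerate by definition
        return 0.0, 1.0

    f_obs = _f_stat(v, codes, k)

    if _n_assignments(counts) <= exhaustive_limit:
        f_null = np.array(
            [_f_stat(v, c, k) for c in _enumerate_assignments(n, counts)]
        )
        p = float((f_null >= f_obs - _EPS).mean())
        return f_obs, p

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f_null = _mc_f_null(v, counts, n_perm, rng)
    p = float((1 + (f_null >= f_obs - _EPS).sum()) / (1 + n_perm))
    return f_obs, p


def _mc_f_null(v: np.ndarray, counts: list[int], n_perm: int, rng) -> np.ndarray:
    """Vectorized Monte-Carlo null F values: permute the value vector and
    read group membership off fixed column blocks."""
    n, k = len(v), len(counts)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    P = v[perm]  # (n_perm, n)
    grand = P.mean(axis=1)
    sst = ((P - grand[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(n_perm)
    b0 = 0
    for c in counts:
        gm = P[:, b0 : b0 + c].mean(axis=1)
        ssb += c * (gm - grand) ** 2
        b0 += c
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f[(ssw <= 0) & (ssb > 0)] = np.inf
    f[sst <= 0] = 0.0
    return f


# ---------------------------------------------------------------------------
# Multiple testing, fold change, selection
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1),
    returned in the input order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fold_change(group_means: dict[str, float]) -> float:
    """Maximal pairwise linear-scale ratio between group means given on the
    log2 scale: ``2 ** (max - min)``; always >= 1."""
    means = [v for v in group_means.values() if not np.isnan(v)]
    if len(means) < 2:
        raise ValueError("fold change needs >= 2 defined group means")
    return float(2.0 ** (max(means) - min(means)))


def select_significant(
    results: pd.DataFrame, alpha: float = 0.05, fc_min: float = 1.5
) -> pd.DataFrame:
    """Features with adjusted p <= alpha AND fold change >= fc_min, stably
    ordered by (p_adj, feature_id). Boundary values are included."""
    sel = results[(results["p_adj"] <= alpha) & (results["fc"] >= fc_min)]
    return sel.sort_values(["p_adj", "feature_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Matrix-level driver
# ---------------------------------------------------------------------------

def diff_test(
    m: QuantMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive_limit: int = 20000,
    min_per_group: int = 2,
    exclude_groups: tuple[str, ...] = ("UNC",),
) -> pd.DataFrame:
    """Per-feature permutation ANOVA over a quant matrix.

    ``groups`` maps sample_id -> group label; samples in ``exclude_groups``
    (by default the unclassified ones) are left out. Features that cannot be
    tested (fewer than two groups with ``min_per_group`` present values)
    appear with ``tested = False`` and NaN statistics.
    """
    if m.scale != "log2":
        raise ValueError("diff_test expects a log2-scale matrix")
    groups = groups.reindex(m.sample_ids)
    use = ~groups.isin(exclude_groups) & groups.notna()
    data = m.data.loc[:, use.to_numpy()]
    garr = groups[use].to_numpy()
    labels = list(pd.unique(garr))

    rng = np.random.default_rng(seed)
    rows = []
    for fid, vals in data.iterrows():
        v = vals.to_numpy(float)
        gmeans = {
            lab: (np.nanmean(v[garr == lab]) if (~np.isnan(v[garr == lab])).any() else np.nan)
            for lab in labels
        }
        npg = {lab: int((~np.isnan(v[garr == lab])).sum()) for lab in labels}
        tested_means = {
            lab: mu for lab, mu in gmeans.items() if npg[lab] >= min_per_group
        }
        try:
            f, p = perm_anova(
                v, garr, n_perm=n_perm, seed=rng,
                exhaustive_limit=exhaustive_limit, min_per_group=min_per_group,
            )
            fc = fold_change(tested_means)
            tested = True
        except ValueError:
            f = p = fc = np.nan
            tested = False
        row = {"feature_id": fid, "tested": tested, "F": f, "p_perm": p, "fc": fc}
        for lab in labels:
            row[f"mean_{lab}"] = gmeans[lab]
            row[f"n_{lab}"] = npg[lab]
        rows.append(row)

    out = pd.DataFrame(rows)
    tested_mask = out["tested"].to_numpy()
    out["p_adj"] = np.nan
    if tested_mask.any():
        out.loc[tested_mask, "p_adj"] = bh_adjust(out.loc[tested_mask, "p_perm"])
    out["significant"] = tested_mask & (out["p_adj"] <= alpha) & (out["fc"] >= fc_min)
    return out


class PermutationAnova(BaseEstimator):
    """Scikit-learn-style wrapper: univariate permutation-ANOVA feature
    screen usable inside sklearn pipelines.

    ``fit(X, y)`` takes a samples x features array/DataFrame of log2
    abundances (NaN = missing) and group labels ``y``; fitted attributes are
    ``fstat_``, ``pvalues_``, ``pvalues_adj_``, ``fold_change_`` and
    ``significant_``. ``transform(X)`` keeps the significant columns.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        fc_min: float = 1.5,
        n_perm: int = 9999,
        seed: int = 0,
        exhaustive_limit: int = 20000,
        min_per_group: int = 2,
    ):
        self.alpha = alpha
        self.fc_min = fc_min
        self.n_perm = n_perm
        self.seed = seed
        self.exhaustive_limit = exhaustive_limit
        self.min_per_group = min_per_group

    def fit(self, X, y):
        df = pd.DataFrame(X)
        qm = QuantMatrix(df.T, scale="log2")
        groups = pd.Series(np.asarray(y), index=df.index)
        res = diff_test(
            qm, groups, alpha=self.alpha, fc_min=self.fc_min, n_perm=self.n_perm,
            seed=self.seed, exhaustive_limit=self.exhaustive_limit,
            min_per_group=self.min_per_group, exclude_groups=(),
        )
        self.results_ = res
        self.fstat_ = res["F"].to_numpy()
        self.pvalues_ = res["p_perm"].to_numpy()
        self.pvalues_adj_ = res["p_adj"].to_numpy()
        self.fold_change_ = res["fc"].to_numpy()
        self.significant_ = res["significant"].to_numpy()
        return self

    def transform(self, X):
        df = pd.DataFrame(X)
        return df.loc[:, self.significant_]
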