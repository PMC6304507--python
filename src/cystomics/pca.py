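"""SVD-based PCA of quantitative profiles and supergroup assignment.

The cyst types separate along the first principal component into two
"supergroups" — pseudocyst/IPMN versus carcinoma/serous/mucinous — and
unclassified samples are assigned by projecting them onto the fitted
component and taking the nearer supergroup centroid on PC1.

Features are centered but not variance-scaled (log2 abundances are already
on a common scale). Missingness policy: either restrict the model to
features complete in all fitted samples ("complete", the default) or impute
per-feature means ("mean_impute"). Loadings carry a deterministic sign
convention: each column's largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import QuantMatrix


@dataclass
class PCAModel:
    feature_ids: list[str]
    center: pd.Series                 # per-feature offsets subtracted before SVD
    loadings: pd.DataFrame            # feature x component, orthonormal columns
    scores: pd.DataFrame              # fitted sample x component
    variance_explained: np.ndarray    # fraction per retained component
    singular_values: np.ndarray
    complete_policy: str = "complete"


def _usable_matrix(m: QuantMatrix, policy: str, min_present_frac: float) -> pd.DataFrame:
    data = m.data
    if min_present_frac > 0:
        data = data.loc[data.notna().mean(axis=1) >= min_present_frac]
    if policy == "complete":
        df = data.dropna(axis=0)
    elif policy == "mean_impute":
        means = data.mean(axis=1, skipna=True)
        df = data.apply(lambda col: col.fillna(means))
        df = df.dropna(axis=0)  # features missing everywhere stay unusable
    else:
        raise ValueError(f"unknown complete_policy {policy!r}")
    return df


def pca_fit(m: QuantMatrix, complete_policy: str = "complete",
            n_components: int | None = None,
            min_present_frac: float = 0.0) -> PCAModel:
    """Fit PCA by SVD of the feature-centered matrix (samples as rows).

    ``min_present_frac`` optionally restricts the model to features present
    in at least that fraction of samples before the missingness policy is
    applied (useful with ``mean_impute`` on sparse degradome matrices)."""
    if m.scale != "log2":
        raise ValueError("pca_fit expects a log2-scale matrix")
    if len(m.sample_ids) < 2:
        raise ValueError("PCA needs at least 2 samples")
    df = _usable_matrix(m, complete_policy, min_present_frac)
    if df.shape[0] < 2:
        raise ValueError(
            f"only {df.shape[0]} usable features under policy {complete_policy!r}"
        )
    center = df.mean(axis=1)
    X = (df.sub(center, axis=0)).T.to_numpy()  # samples x features
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    # sign convention: largest-|entry| of each loading column positive
    V = Vt.T[:, :k]
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = X @ V
    var = s**2 / (s**2).sum()
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAModel(
        feature_ids=list(df.index),
        center=center,
        loadings=pd.DataFrame(V, index=df.index, columns=comp),
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comp),
        variance_explained=var[:k],
        singular_values=s[:k],
        complete_policy=complete_policy,
    )


def pca_project(model: PCAModel, m: QuantMatrix) -> pd.DataFrame:
    """Project new samples onto the fitted components:
    scores = (values - centering offsets) . loadings."""
    df = m.data.reindex(model.feature_ids)
    if model.complete_policy == "mean_impute":
        df = df.apply(lambda col: col.fillna(model.center))
    missing = df.index[df.isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"new samples lack values for model features: {list(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    X = df.sub(model.center, axis=0).T.to_numpy()
    return pd.DataFrame(
        X @ model.loadings.to_numpy(), index=m.sample_ids, columns=model.loadings.columns
    )


def assign_supergroup(
    model: PCAModel,
    labeled_groups: pd.Series,
    supergroups: tuple[tuple[str, ...], tuple[str, ...]],
    unc_scores: pd.DataFrame,
) -> pd.DataFrame:
    """Nearest-PC1-centroid assignment of unclassified samples.

    Centroids are the mean PC1 scores of the labeled samples of each
    supergroup. Returns a frame with pc1, distances, the assigned supergroup
    (None on exact ties or coincident centroids) and the margin.
    """
    sg_a, sg_b = supergroups
    name_a, name_b = "|".join(sg_a), "|".join(sg_b)
    pc1 = model.scores["PC1"]
    lab = labeled_groups.reindex(pc1.index)
    cent_a = pc1[lab.isin(sg_a)].mean()
    cent_b = pc1[lab.isin(sg_b)].mean()
    if np.isnan(cent_a) or np.isnan(cent_b):
        raise ValueError("both supergroups need labeled samples")
    rows = []
    for sid, x in unc_scores["PC1"].items():
        da, db = abs(x - cent_a), abs(x - cent_b)
        if cent_a == cent_b or da == db:
            assigned = None
        else:
            assigned = name_a if da < db else name_b
        rows.append((sid, float(x), float(da), float(db), assigned, float(abs(da - db))))
    return pd.DataFrame(
        rows, columns=["sample_id", "pc1", f"dist_{name_a}", f"dist_{name_b}",
                       "assigned", "margin"],
    ).set_index("sample_id")


class SupergroupClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style classifier: PCA on the training cohort, then
    nearest-PC1-centroid prediction of the supergroup.

    ``fit(X, y)`` takes samples x features log2 abundances and per-sample
    supergroup labels (any two label values); ``predict(X)`` projects new
    samples and returns the nearer centroid's label.
    """

    def __init__(self, complete_policy: str = "complete"):
        self.complete_policy = complete_policy

    def fit(self, X, y):
        df = pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("SupergroupClassifier expects exactly 2 classes")
        qm = QuantMatrix(df.T, scale="log2")
        self.model_ = pca_fit(qm, complete_policy=self.complete_policy)
        pc1 = self.model_.scores["PC1"].to_numpy()
        self.centroids_ = {c: pc1[y == c].mean() for c in self.classes_}
        return self

    def predict(self, X):
        df = pd.DataFrame(X)
        qm = QuantMatrix(df.T, scale="log2")
        pc1 = pca_project(self.model_, qm)["PC1"].to_numpy()
        c0, c1 = self.classes_
        d0 = np.abs(pc1 - self.centroids_[c0])
        d1 = np.abs(pc1 - self.centroids_[c1])
        return np.where(d0 <= d1, c0, c1)
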