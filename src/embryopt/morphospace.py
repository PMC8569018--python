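"""The morphospace: scaled PCA of descriptor vectors plus severity clustering.

Descriptors are z-scored feature-wise and decomposed by SVD; the model
records loadings, per-component variance explained (percent, summing to
100), per-variable contributions to PC1/PC2, and the training scores.
New cohorts can be projected into a fitted space. Embryos are grouped
into severity clusters (default k = 4: unperturbed, slightly, moderately
and heavily perturbed) with hierarchical (Ward), k-means or k-medoids
clustering; the three methods are expected to give similar partitions on
well-separated data. Cluster labels are renumbered by ascending mean PC1
score so that label order tracks severity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class MorphospaceModel:
    feature_names: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    loadings: np.ndarray            # (n_features, n_components), orthonormal columns
    variance_explained: np.ndarray  # percent per component, sums to 100
    scores: np.ndarray              # (n_embryos, n_components)
    embryo_ids: list[str] = field(default_factory=list)
    contributions: pd.DataFrame | None = None  # % per variable for PC1/PC2
    scaled_training: np.ndarray | None = None

    def to_json(self, path) -> None:
        obj = {
            "feature_names": list(self.feature_names),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_explained": self.variance_explained.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class ClusterAssignment:
    embryo_ids: list[str]
    labels: np.ndarray  # 1..k
    method: str
    k: int
    seed: int | None = None

    def as_dict(self) -> dict[str, int]:
        return {e: int(l) for e, l in zip(self.embryo_ids, self.labels)}


def _scale(X: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return (X - means) / scales


def fit_morphospace(descriptors: pd.DataFrame,
                    selected_features: list[str] | None = None) -> MorphospaceModel:
    """Scale selected descriptor columns and fit a PCA morphospace.

    Rows containing missing values in the selected features are dropped
    with a warning. Features are z-scored (mean 0, SD 1, ddof=1 as in R's
    ``prcomp(scale.=TRUE)``); a zero-variance feature is an error. The
    per-variable contribution to a component is its squared loading,
    normalized to 100% within the component.
    """
    if selected_features is None:
        selected_features = [c for c in descriptors.columns
                             if c not in ("embryo_id", "group_label")]
    missing_cols = [c for c in selected_features if c not in descriptors.columns]
    if missing_cols:
        raise ValueError(f"descriptor table lacks features: {missing_cols}")
    sub = descriptors[selected_features].astype(float)
    keep = ~sub.isna().any(axis=1)
    if not keep.all():
        dropped = descriptors.loc[~keep, "embryo_id"].tolist() \
            if "embryo_id" in descriptors else list(np.flatnonzero(~keep))
        warnings.warn(f"dropping {int((~keep).sum())} rows with missing descriptor "
                      f"values: {dropped}", stacklevel=2)
    sub = sub.loc[keep]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 embryos to fit a morphospace; have {len(sub)}")
    X = sub.to_numpy()
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    zero = [f for f, s in zip(selected_features, scales) if s == 0]
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    Z = _scale(X, means, scales)

    # PCA by SVD of the scaled matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt.T
    scores = Z @ loadings
    var = s**2
    variance_explained = 100.0 * var / var.sum()

    contrib = pd.DataFrame(
        {f"PC{k + 1}": 100.0 * loadings[:, k] ** 2 / np.sum(loadings[:, k] ** 2)
         for k in range(min(2, loadings.shape[1]))},
        index=selected_features)

    ids = descriptors.loc[keep, "embryo_id"].astype(str).tolist() \
        if "embryo_id" in descriptors else [str(i) for i in range(len(sub))]
    return MorphospaceModel(
        feature_names=list(selected_features), feature_means=means,
        feature_scales=scales, loadings=loadings,
        variance_explained=variance_explained, scores=scores,
        embryo_ids=ids, contributions=contrib, scaled_training=Z)


def project_samples(model: MorphospaceModel, new_descriptors: pd.DataFrame) -> np.ndarray:
    """Project new descriptor rows into a fitted morphospace."""
    missing = [f for f in model.feature_names if f not in new_descriptors.columns]
    if missing:
        raise ValueError(f"missing feature(s) in projection table: {missing}")
    X = new_descriptors[model.feature_names].to_numpy(dtype=float)
    return _scale(X, model.feature_means, model.feature_scales) @ model.loadings


def _kmedoids_pam(X: np.ndarray, k: int, seed: int, max_iter: int = 300) -> np.ndarray:
    """Exact-swap PAM k-medoids on Euclidean distances (small n)."""
    rng = np.random.default_rng(seed)
    n = len(X)
    dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    medoids = list(rng.choice(n, size=k, replace=False))
    cost = dist[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                c = dist[:, trial].min(axis=1).sum()
                if c < cost - 1e-12:
                    medoids, cost, improved = trial, c, True
        if not improved:
            break
    return dist[:, medoids].argmin(axis=1)


def cluster_embryos(model: MorphospaceModel, method: str = "hierarchical",
                    k: int = 4, seed: int = 0,
                    space: str = "descriptors") -> ClusterAssignment:
    """Group embryos into severity clusters.

    ``method`` is one of hierarchical (Ward linkage, Euclidean), k-means
    or k-medoids; clustering runs on the scaled descriptors by default
    (``space="scores"`` switches to PC scores). Labels 1..k are ordered
    by ascending mean PC1 score, i.e. by severity along the first axis.
    """
    n = len(model.scores)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of embryos ({n})")
    X = model.scaled_training if space == "descriptors" else model.scores
    if X is None:
        raise ValueError("model lacks training data for clustering")

    if k == 1:
        raw = np.zeros(n, dtype=int)
    elif method == "hierarchical":
        raw = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust") - 1
    elif method == "k-means":
        raw = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    elif method == "k-medoids":
        raw = _kmedoids_pam(X, k, seed)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")

    # renumber 1..k by ascending mean PC1 score (severity order)
    pc1 = model.scores[:, 0]
    present = np.unique(raw)
    order = sorted(present, key=lambda c: pc1[raw == c].mean())
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel[c] for c in raw], dtype=int)
    return ClusterAssignment(embryo_ids=list(model.embryo_ids), labels=labels,
                             method=method, k=k, seed=seed)
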