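"""Motility-phenotype structure: standardized feature matrices, PCA, k-means,
hierarchical clustering and silhouette scoring.

Two feature sets are used: the kinematic set (IR, DR, AS) and the dynamic set
(rmsf α, correlation time in minutes, DFA γ, MSD β, ApEn summary).  Because
the features mix units (mm, mm/s, dimensionless exponents), columns are
z-scored before any distance computation; the dynamic set is additionally
reduced to its leading principal components before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score as _sk_silhouette

KINEMATIC_FEATURES = ("ir", "dr", "as_speed")
DYNAMIC_FEATURES = ("alpha", "corr_minutes", "gamma", "beta", "apen")

FEATURE_SETS = {"kinematic": KINEMATIC_FEATURES, "dynamic": DYNAMIC_FEATURES}


@dataclass
class FeatureMatrix:
    """z-scored cells x metrics matrix with its standardization record."""

    values: np.ndarray                 # standardized, rows = cells
    columns: tuple[str, ...]
    labels: pd.DataFrame               # species / scenario per retained row
    column_mean: np.ndarray
    column_sd: np.ndarray
    n_dropped: int                     # rows removed for undefined metrics


@dataclass
class ClusterSolution:
    """Assignments, centroids (in standardized feature space), silhouette and
    per-cluster label composition."""

    k: int
    assignments: np.ndarray            # values in 1..k
    centroids: np.ndarray
    silhouette: float                  # NaN when k == 1
    composition: pd.DataFrame          # rows = clusters, proportion columns
    method: str
    inertia: float | None = None


def build_features(metrics: pd.DataFrame, feature_set: str = "kinematic",
                   label_columns: tuple[str, ...] = ("species", "scenario")) -> FeatureMatrix:
    """Select, clean and z-score the requested metric columns.

    Rows with any undefined (NaN/inf) metric are dropped (count recorded);
    a column that is entirely undefined or constant raises ``ValueError``.
    """
    try:
        cols = FEATURE_SETS[feature_set]
    except KeyError:
        raise ValueError(f"unknown feature set {feature_set!r}") from None
    missing = [c for c in cols if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing column(s): {missing}")
    sub = metrics[list(cols)].apply(pd.to_numeric)
    finite = np.isfinite(sub.to_numpy()).all(axis=1)
    n_dropped = int((~finite).sum())
    sub = sub.loc[finite]
    if sub.empty:
        raise ValueError("no rows with fully defined metrics")
    mean = sub.mean().to_numpy()
    sd = sub.std(ddof=0).to_numpy()
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant (zero-variance) column(s): {bad}")
    values = (sub.to_numpy() - mean) / sd
    labels = metrics.loc[finite, [c for c in label_columns if c in metrics.columns]]
    return FeatureMatrix(values=values, columns=cols, labels=labels.reset_index(drop=True),
                         column_mean=mean, column_sd=sd, n_dropped=n_dropped)


def pca_reduce(fm: FeatureMatrix, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of the standardized matrix and per-component variance fractions."""
    if n_components > fm.values.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds {fm.values.shape[1]} columns"
        )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(fm.values)
    return scores, pca.explained_variance_ratio_


def _composition(assignments: np.ndarray, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster proportions of each label value; rows sum to 1 per label column."""
    out = {}
    for col in labels.columns:
        tab = pd.crosstab(assignments, labels[col].to_numpy(), normalize="index")
        out.update({f"{col}:{val}": tab[val] for val in tab.columns})
    comp = pd.DataFrame(out)
    comp.index.name = "cluster"
    return comp


def silhouette(points: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient (b − a)/max(a, b); singletons contribute 0."""
    labels = np.unique(assignments)
    if len(labels) < 2:
        raise ValueError("silhouette needs at least two clusters")
    if len(labels) == len(assignments):
        return 0.0  # all singletons: every point contributes 0 by convention
    return float(_sk_silhouette(points, assignments))


def kmeans_cluster(points: np.ndarray, k: int, labels: pd.DataFrame | None = None,
                   n_init: int = 50, seed: int = 0) -> ClusterSolution:
    """Lloyd k-means with k-means++ seeding, best of ``n_init`` restarts by inertia."""
    points = np.asarray(points, dtype=float)
    if len(points) < k:
        raise ValueError(f"need at least k={k} points, got {len(points)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(points)
    assignments = raw + 1
    sil = silhouette(points, assignments) if k > 1 else float("nan")
    if labels is None:
        labels = pd.DataFrame(index=range(len(points)))
    return ClusterSolution(
        k=k, assignments=assignments, centroids=km.cluster_centers_,
        silhouette=sil, composition=_composition(assignments, labels),
        method="kmeans", inertia=float(km.inertia_),
    )


def hierarchical_cluster(points: np.ndarray, k: int, labels: pd.DataFrame | None = None,
                         linkage: str = "ward") -> ClusterSolution:
    """Agglomerative clustering (ward/average/complete), tree cut at k clusters."""
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    points = np.asarray(points, dtype=float)
    if len(points) < k:
        raise ValueError(f"need at least k={k} points, got {len(points)}")
    model = AgglomerativeClustering(n_clusters=k, linkage=linkage)
    assignments = model.fit_predict(points) + 1
    centroids = np.vstack([points[assignments == c].mean(axis=0)
                           for c in range(1, k + 1)])
    sil = silhouette(points, assignments) if k > 1 else float("nan")
    if labels is None:
        labels = pd.DataFrame(index=range(len(points)))
    return ClusterSolution(
        k=k, assignments=assignments, centroids=centroids, silhouette=sil,
        composition=_composition(assignments, labels), method=f"hierarchical-{linkage}",
    )
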