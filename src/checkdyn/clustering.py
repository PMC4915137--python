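"""Ward hierarchical clustering of per-unit encoding features.

Each unit is summarized by a three-dimensional feature vector of signed
maximal Wald Z values — feedback, Check-vs-Work, cued side — taken from the
sliding-GLM classification, with zeros for factors the unit did not
significantly encode.  Agglomerative clustering with Euclidean distance and
Ward linkage groups units into functional classes; the tree is cut either
at the largest dendrogram height gap or into a fixed number of clusters.
Features are not standardized by default (the signed Z values are already
on a common scale); an optional flag z-scores them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

FEATURE_TERMS = ("feedback", "checkwork", "space")


def feature_matrix(
    classification: pd.DataFrame, terms: tuple[str, ...] = FEATURE_TERMS
) -> pd.DataFrame:
    """Signed max-Z feature matrix (units x terms) from a classification table.

    Zeros appear exactly where a unit is not significant for a term.
    """
    cols = {}
    for t in terms:
        col = f"{t}_signed_max_z"
        if col not in classification.columns:
            raise KeyError(f"classification table lacks {col}")
        cols[t] = classification[col].fillna(0.0).to_numpy(float)
    return pd.DataFrame(cols, index=classification["unit_id"].to_numpy())


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1-based cluster labels per unit
    linkage: np.ndarray  # scipy linkage matrix
    n_clusters: int
    cut_height: float | None


def ward_cluster(
    features: pd.DataFrame | np.ndarray,
    cut: int | str = "gap",
    standardize: bool = False,
) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering with a gap or fixed-k cut.

    ``cut`` is either an integer k or ``"gap"``, which places the threshold
    in the largest gap between successive merge heights (above small
    distances, below the large jumps).  Deterministic given input order.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 units")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    if isinstance(cut, (int, np.integer)):
        k = int(cut)
        if k > len(X):
            raise ValueError(f"k={k} exceeds the number of units ({len(X)})")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        height = None
    elif cut == "gap":
        heights = Z[:, 2]
        if len(heights) == 1 or np.allclose(heights, heights[0]):
            labels = np.ones(len(X), dtype=int)
            height = float(heights[-1]) + 1.0
        else:
            gaps = np.diff(heights)
            j = int(np.argmax(gaps))
            height = float((heights[j] + heights[j + 1]) / 2.0)
            labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        raise ValueError("cut must be an integer k or 'gap'")
    return ClusterResult(
        labels=np.asarray(labels),
        linkage=Z,
        n_clusters=int(len(np.unique(labels))),
        cut_height=height,
    )


def characterize_clusters(
    labels: np.ndarray,
    features: pd.DataFrame,
    rates: pd.DataFrame | None = None,
    joint_z_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster mean feature vector (and mean firing profile if given).

    Flags clusters jointly loaded on negative feedback and on Check — i.e.
    mean feedback feature <= -threshold together with mean checkwork feature
    >= +threshold — the phenotype linking performance monitoring with the
    decision to check.
    """
    feats = pd.DataFrame(np.asarray(features, float), columns=list(features.columns))
    feats["cluster"] = np.asarray(labels)
    out = feats.groupby("cluster").agg(["mean", "count"])
    summary = pd.DataFrame(
        {
            "cluster": out.index.to_numpy(),
            "n_units": out[(feats.columns[0], "count")].to_numpy(),
        }
    )
    for c in features.columns:
        summary[f"mean_{c}"] = out[(c, "mean")].to_numpy()
    if {"feedback", "checkwork"} <= set(features.columns):
        summary["neg_feedback_and_check"] = (
            (summary["mean_feedback"] <= -joint_z_threshold)
            & (summary["mean_checkwork"] >= joint_z_threshold)
        )
    if rates is not None:
        rate_mean = (
            pd.DataFrame(np.asarray(rates, float))
            .assign(cluster=np.asarray(labels))
            .groupby("cluster")
            .mean()
        )
        for col in rate_mean.columns:
            summary[f"mean_rate_{col}"] = rate_mean[col].to_numpy()
    return summary


def within_cluster_sse(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared Euclidean errors."""
    X = np.asarray(X, float)
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return total
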