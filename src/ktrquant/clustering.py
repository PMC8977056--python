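"""Trajectory clustering and multi-metric internal validation.

Clusters cells by their normalized C/N trajectories over the response
window (time points 9-18) using hierarchical clustering (Manhattan or
Euclidean distances, Ward or Ward2 linkage) and k-means, and scores every
(method, k) combination with six internal validation metrics:

* BW ratio - mean between-cluster pairwise distance over the cluster-size
  weighted mean of within-cluster mean pairwise distances (higher better);
* Dunn index; average silhouette width; Pearson gamma (correlation of
  distances with the different-cluster indicator); Calinski-Harabasz
  variance ratio (coordinate space); and connectivity (a lower-is-better
  neighborhood penalty with neighborhood size 25).

Each metric is normalized by its maximum over the candidate grid (five
methods x three k values = 15 combinations per kinase) and the six
normalized values summed into a combined score; the top score, ties broken
toward fewer clusters, selects the clustering. Connectivity is inverted to
1/(1 + connectivity) before normalization so that higher is better for
every summand (its raw value is reported alongside).

Ward2 squares the supplied dissimilarities before applying the Ward
minimum-variance update (and reports square-rooted merge heights); with
Euclidean input it coincides with classic coordinate-space Ward. Plain
Ward applies the update to the dissimilarities as given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

logger = logging.getLogger(__name__)

METRIC_NAMES = ("bw", "dunn", "avg_silhouette", "pearson_gamma",
                "calinski_harabasz", "connectivity")


def pairwise_distances(matrix: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric pairwise distance matrix of rows (L1 or L2)."""
    matrix = np.asarray(matrix, dtype=float)
    if np.isnan(matrix).any():
        raise ValueError("matrix contains NaN entries")
    if metric not in ("manhattan", "euclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    name = "cityblock" if metric == "manhattan" else "euclidean"
    return squareform(pdist(matrix, metric=name))


@dataclass
class ClusterResult:
    """A partition of the trajectory matrix rows.

    ``labels`` are 1..k; ``method`` is 'hier' or 'kmeans'; for hierarchical
    results ``distance`` and ``linkage`` record the dissimilarity and the
    Ward variant used.
    """

    labels: np.ndarray
    method: str
    k: int
    distance: str = "euclidean"
    linkage: str = "none"
    seed: int | None = None
    inertia: float | None = None

    @property
    def name(self) -> str:
        if self.method == "kmeans":
            return f"kmeans_k{self.k}"
        return f"hier_{self.distance}_{self.linkage}_k{self.k}"


def hierarchical_cluster(dist: np.ndarray, linkage_method: str = "ward2",
                         k: int = 2, distance_name: str = "euclidean") -> ClusterResult:
    """Cut a Ward/Ward2 dendrogram of a precomputed distance matrix into k clusters.

    scipy's 'ward' linkage on a condensed distance vector squares the
    inputs, applies the Lance-Williams Ward update, and reports
    square-rooted heights - exactly the Ward2 recipe. Plain Ward (the
    update applied to the raw dissimilarities) is obtained by feeding the
    square roots of the dissimilarities through the same routine; the cut
    into k clusters is invariant to the monotone height transform.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    condensed = squareform(dist, checks=False)
    if linkage_method == "ward2":
        Z = linkage(condensed, method="ward")
    elif linkage_method == "ward":
        Z = linkage(np.sqrt(condensed), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=np.asarray(labels), method="hier", k=k,
                         distance=distance_name, linkage=linkage_method)


def kmeans_cluster(matrix: np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 25) -> ClusterResult:
    """Best-of-``n_restarts`` Lloyd k-means on the trajectory matrix.

    Deterministic given the seed; empty clusters are repaired by sklearn's
    standard re-seeding.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(matrix)
    return ClusterResult(labels=km.labels_ + 1, method="kmeans", k=k,
                         distance="euclidean", seed=seed,
                         inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# Validation metrics


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    return labels


def bw_ratio(dist: np.ndarray, labels: np.ndarray) -> float:
    """Between/within distance ratio.

    B = mean distance over all between-cluster pairs; for each cluster c
    with n_c >= 2 members, w_c = mean within-cluster pairwise distance and
    W = sum(n_c * w_c) / sum(n_c) over those clusters; returns B / W.
    Higher values indicate better-separated, tighter clusters.
    """
    labels = _check_labels(labels)
    dist = np.asarray(dist, dtype=float)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    between = dist[iu][~same[iu]]
    if between.size == 0:
        raise ValueError("no between-cluster pairs")
    B = float(between.mean())
    num = den = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            continue
        sub = dist[np.ix_(members, members)]
        w_c = float(sub[np.triu_indices(len(members), k=1)].mean())
        num += len(members) * w_c
        den += len(members)
    if den == 0:
        raise ValueError("all clusters are singletons; BW undefined")
    W = num / den
    if W == 0:
        raise ValueError("zero within-cluster distances; BW undefined")
    return B / W


def dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster distance over max intra-cluster diameter."""
    labels = _check_labels(labels)
    dist = np.asarray(dist, dtype=float)
    uniq = np.unique(labels)
    diam = 0.0
    for c in uniq:
        members = np.flatnonzero(labels == c)
        if len(members) >= 2:
            diam = max(diam, float(dist[np.ix_(members, members)].max()))
    if diam == 0:
        raise ValueError("zero maximal intra-cluster diameter; Dunn undefined")
    sep = np.inf
    for i, c1 in enumerate(uniq):
        for c2 in uniq[i + 1:]:
            m1 = np.flatnonzero(labels == c1)
            m2 = np.flatnonzero(labels == c2)
            sep = min(sep, float(dist[np.ix_(m1, m2)].min()))
    return sep / diam


def avg_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from a precomputed distance matrix.

    s(i) = (b - a) / max(a, b) with a = mean distance to own cluster
    (excluding self) and b = smallest mean distance to another cluster;
    singleton points contribute 0.
    """
    labels = _check_labels(labels)
    return float(silhouette_score(np.asarray(dist, dtype=float), labels,
                                  metric="precomputed"))


def pearson_gamma(dist: np.ndarray, labels: np.ndarray) -> float:
    """Pearson correlation of pairwise distances with the split indicator.

    The indicator is 1 for pairs in different clusters, 0 for same-cluster
    pairs; high values mean large distances align with cluster boundaries.
    """
    labels = _check_labels(labels)
    dist = np.asarray(dist, dtype=float)
    iu = np.triu_indices(len(labels), k=1)
    d = dist[iu]
    ind = (labels[:, None] != labels[None, :])[iu].astype(float)
    if np.all(d == d[0]):
        raise ValueError("constant distance vector; Pearson gamma undefined")
    return float(pearsonr(d, ind)[0])


def calinski_harabasz(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion (between SS / (k-1)) / (within SS / (n-k)).

    Computed in coordinate space for every combination, including those
    clustered with Manhattan distances.
    """
    labels = _check_labels(labels)
    matrix = np.asarray(matrix, dtype=float)
    n, k = len(labels), len(np.unique(labels))
    if n == k:
        raise ValueError("n == k; Calinski-Harabasz undefined")
    within = 0.0
    for c in np.unique(labels):
        sub = matrix[labels == c]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    if within == 0:
        raise ValueError("zero within-cluster variance; Calinski-Harabasz infinite")
    return float(calinski_harabasz_score(matrix, labels))


def connectivity(dist: np.ndarray, labels: np.ndarray, L: int = 25) -> float:
    """Neighborhood penalty: sum of 1/j over cross-cluster j-th nearest neighbors.

    For each point, its L nearest neighbors are ranked by distance (ties
    broken by index order); each rank-j neighbor in a different cluster
    adds 1/j. Lower is better; 0 means every point's L-neighborhood is
    pure.
    """
    labels = np.asarray(labels)
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    L_eff = min(L, n - 1)
    total = 0.0
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        order = order[order != i][:L_eff]
        ranks = np.arange(1, len(order) + 1)
        total += float((1.0 / ranks)[labels[order] != labels[i]].sum())
    return total


def compute_validation_metrics(matrix: np.ndarray, dist: np.ndarray,
                               labels: np.ndarray, L: int = 25) -> dict[str, float]:
    """All six metrics for one clustering."""
    return {
        "bw": bw_ratio(dist, labels),
        "dunn": dunn_index(dist, labels),
        "avg_silhouette": avg_silhouette(dist, labels),
        "pearson_gamma": pearson_gamma(dist, labels),
        "calinski_harabasz": calinski_harabasz(matrix, labels),
        "connectivity": connectivity(dist, labels, L=L),
    }


# ---------------------------------------------------------------------------
# The (method, k) candidate grid and combined-score selection

HIER_METHODS = (("manhattan", "ward"), ("manhattan", "ward2"),
                ("euclidean", "ward"), ("euclidean", "ward2"))


def candidate_grid(ks: tuple[int, ...]) -> list[dict]:
    """The five methods at each candidate k (15 combinations for 3 ks)."""
    grid = []
    for k in ks:
        for distance_name, link in HIER_METHODS:
            grid.append({"method": "hier", "distance": distance_name,
                         "linkage": link, "k": k})
        grid.append({"method": "kmeans", "distance": "euclidean",
                     "linkage": "none", "k": k})
    return grid


def run_grid(matrix: np.ndarray, ks: tuple[int, ...], seed: int = 0,
             n_restarts: int = 25, neighborhood: int = 25):
    """Cluster with every grid combination and score with all six metrics.

    Returns (report DataFrame, dict name -> ClusterResult). The report has
    one row per combination with the raw metric values.
    """
    dists = {name: pairwise_distances(matrix, name)
             for name in ("manhattan", "euclidean")}
    rows = []
    results: dict[str, ClusterResult] = {}
    for spec in candidate_grid(ks):
        if spec["method"] == "hier":
            res = hierarchical_cluster(dists[spec["distance"]],
                                       linkage_method=spec["linkage"],
                                       k=spec["k"],
                                       distance_name=spec["distance"])
        else:
            res = kmeans_cluster(matrix, spec["k"], seed=seed,
                                 n_restarts=n_restarts)
        metrics = compute_validation_metrics(matrix, dists[res.distance],
                                             res.labels, L=neighborhood)
        rows.append({"combination": res.name, **spec, **metrics})
        results[res.name] = res
    return pd.DataFrame(rows), results


def combine_metric_scores(report: pd.DataFrame) -> pd.DataFrame:
    """Max-normalize the six metrics across combinations and sum them.

    Connectivity (lower is better) is first transformed to
    1/(1 + connectivity) so that all summands reward good clusterings;
    each metric is divided by its maximum over the combinations, and the
    combined score is the sum of the normalized values. Output is ranked
    by score, ties broken toward fewer clusters. Metrics whose maximum is
    not positive are dropped with a warning.
    """
    out = report.copy()
    out["connectivity_raw"] = out["connectivity"]
    out["connectivity"] = 1.0 / (1.0 + out["connectivity_raw"])
    score = np.zeros(len(out))
    for m in METRIC_NAMES:
        mx = out[m].max()
        if not mx > 0:
            logger.warning("combine_metric_scores: dropping metric %r (max <= 0)", m)
            out[f"norm_{m}"] = np.nan
            continue
        out[f"norm_{m}"] = out[m] / mx
        score += out[f"norm_{m}"].to_numpy()
    out["combined_score"] = score
    out = out.sort_values(["combined_score", "k"],
                          ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def select_clustering(matrix: np.ndarray, ks: tuple[int, ...], seed: int = 0,
                      **kwargs):
    """Full validation/selection: grid, metrics, combined score, best result.

    Returns (scored report, best ClusterResult, all results).
    """
    report, results = run_grid(matrix, ks, seed=seed, **kwargs)
    scored = combine_metric_scores(report)
    best = results[scored.iloc[0]["combination"]]
    return scored, best, results


# ---------------------------------------------------------------------------
# Downstream summaries


def cluster_condition_distribution(labels: np.ndarray,
                                   conditions) -> pd.DataFrame:
    """Per-condition fraction of cells in each cluster (rows sum to 1)."""
    df = pd.DataFrame({"cluster": np.asarray(labels), "condition": np.asarray(conditions)})
    counts = df.value_counts(["condition", "cluster"]).unstack(fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    return frac


def cluster_cooccurrence(erk_labels: np.ndarray, akt_labels: np.ndarray,
                         conditions) -> pd.DataFrame:
    """Joint (ERK cluster x Akt cluster) fractions per condition.

    The two marginals of each condition's joint table equal the
    single-kinase cluster distributions exactly.
    """
    erk_labels = np.asarray(erk_labels)
    akt_labels = np.asarray(akt_labels)
    if len(erk_labels) != len(akt_labels):
        raise ValueError("ERK and Akt label vectors must cover the same cells")
    df = pd.DataFrame({"erk_cluster": erk_labels, "akt_cluster": akt_labels,
                       "condition": np.asarray(conditions)})
    joint = (df.value_counts(["condition", "erk_cluster", "akt_cluster"])
             .rename("count").reset_index())
    totals = joint.groupby("condition")["count"].transform("sum")
    joint["fraction"] = joint["count"] / totals
    return joint
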