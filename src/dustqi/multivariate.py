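"""Multivariate site assessment: normalization, k-selection, k-means and
hierarchical clustering with cophenetic linkage selection, clusterwise
bootstrap Jaccard stability, PCA, and partition comparison.

The clustering stage cross-validates k-means against hierarchical
agglomeration on Euclidean distances: the number of clusters is chosen
by mean silhouette width (the elbow curve is reported for inspection),
the linkage is chosen by cophenetic correlation, and the final partition
is stress-tested by resampling sites with replacement and measuring how
well each original cluster is recovered (best-match Jaccard).  Mean
Jaccard above 0.85 is read as highly stable, 0.60–0.85 as stable;
the dissolution rate (share of replicates recovered below 0.5) is the
matching instability figure.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .tables import ConcentrationTable

__all__ = [
    "Clustering",
    "KSelection",
    "StabilityResult",
    "PCAResult",
    "normalize",
    "select_k",
    "kmeans_partition",
    "hierarchical_partition",
    "bootstrap_stability",
    "pca",
    "compare_partitions",
]

# deterministic preference on cophenetic-correlation ties
LINKAGE_PREFERENCE = ("average", "complete", "ward", "median")


def _as_matrix(data: ConcentrationTable | pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(data, ConcentrationTable):
        return data.data
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr)


def normalize(table: ConcentrationTable | pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Column-wise z-score (default) or min–max scaling to [0, 1].

    Z-scoring uses the sample (n-1) standard deviation; a zero-variance
    column is an error naming the element.
    """
    df = _as_matrix(table)
    if df.shape[0] < 2:
        raise ValueError("normalization needs at least 2 sites")
    if method == "zscore":
        sd = df.std(ddof=1)
        zero = [str(c) for c in df.columns[sd == 0]]
        if zero:
            raise ValueError(f"zero-variance elements cannot be z-scored: {zero}")
        return (df - df.mean()) / sd
    if method == "minmax":
        rng = df.max() - df.min()
        zero = [str(c) for c in df.columns[rng == 0]]
        if zero:
            raise ValueError(f"zero-range elements cannot be min-max scaled: {zero}")
        return (df - df.min()) / rng
    raise ValueError(f"unknown normalization method {method!r}")


@dataclasses.dataclass(frozen=True)
class Clustering:
    """A site partition with method metadata.

    labels are 1..k aligned to ``ids``; for hierarchical results the full
    merge tree (scipy linkage matrix) and per-candidate cophenetic
    correlations are attached.
    """

    ids: tuple
    labels: np.ndarray
    k: int
    method: str
    distance: str = "euclidean"
    inertia: float | None = None
    linkage_matrix: np.ndarray | None = None
    cophenetic: dict[str, float] | None = None
    chosen_linkage: str | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.min() < 1 or labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(np.unique(labels)) != self.k:
            raise ValueError("every cluster must be nonempty")
        object.__setattr__(self, "labels", labels)

    def members(self, cluster: int) -> set:
        return {i for i, lab in zip(self.ids, self.labels) if lab == cluster}


@dataclasses.dataclass(frozen=True)
class KSelection:
    chosen_k: int
    wss: dict[int, float]
    silhouette: dict[int, float]


def _kmeans_fit(matrix: np.ndarray, k: int, seed: int, restarts: int) -> KMeans:
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed,
    )
    km.fit(matrix)
    return km


def select_k(
    matrix: ConcentrationTable | pd.DataFrame | np.ndarray,
    k_max: int,
    seed: int = 0,
    restarts: int = 25,
) -> KSelection:
    """Elbow and silhouette diagnostics over k = 2..k_max.

    The chosen k is the silhouette argmax; the within-cluster sum of
    squares (elbow) curve is returned for inspection, not thresholded.
    """
    df = _as_matrix(matrix)
    n = df.shape[0]
    if not (2 <= k_max <= n - 1):
        raise ValueError("need 2 <= k_max <= n_sites - 1")
    X = df.to_numpy()
    wss, sil = {}, {}
    for k in range(2, k_max + 1):
        km = _kmeans_fit(X, k, seed, restarts)
        wss[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, km.labels_, metric="euclidean"))
    chosen = max(sil, key=lambda k: (sil[k], -k))
    return KSelection(chosen_k=chosen, wss=wss, silhouette=sil)


def kmeans_partition(
    matrix: ConcentrationTable | pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 25,
) -> Clustering:
    """Best-of-``restarts`` Lloyd k-means partition (deterministic per seed)."""
    df = _as_matrix(matrix)
    if k > df.shape[0]:
        raise ValueError("k cannot exceed the number of sites")
    X = df.to_numpy()
    if k == 1:
        labels = np.ones(df.shape[0], dtype=int)
        inertia = float(((X - X.mean(axis=0)) ** 2).sum())
        return Clustering(ids=tuple(df.index), labels=labels, k=1, method="kmeans", inertia=inertia)
    km = _kmeans_fit(X, k, seed, restarts)
    return Clustering(
        ids=tuple(df.index),
        labels=_canonical_labels(km.labels_),
        k=k,
        method="kmeans",
        inertia=float(km.inertia_),
    )


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def select_linkage(cophenetic: dict[str, float]) -> str:
    """Argmax of cophenetic correlation; exact ties fall back to the
    fixed preference order average > complete > ward > median."""
    order = {m: i for i, m in enumerate(LINKAGE_PREFERENCE)}
    return max(cophenetic, key=lambda m: (cophenetic[m], -order.get(m, len(order))))


def hierarchical_partition(
    matrix: ConcentrationTable | pd.DataFrame | np.ndarray,
    k: int,
    linkages: Sequence[str] = LINKAGE_PREFERENCE,
) -> Clustering:
    """Agglomerative partition on Euclidean distances.

    Each candidate linkage is scored by the cophenetic correlation of its
    merge tree against the input distances; the winner (ties broken by
    the fixed preference order average > complete > ward > median) is cut
    into k groups.  "ward" follows the ward.D2 convention: plain
    Euclidean distances in, squared-distance update inside.
    """
    df = _as_matrix(matrix)
    n = df.shape[0]
    if n < 2:
        raise ValueError("hierarchical clustering needs at least 2 sites")
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n_sites")
    dist = pdist(df.to_numpy(), metric="euclidean")
    trees = {}
    coph = {}
    for method in linkages:
        Z = hierarchy.linkage(dist, method=method)
        trees[method] = Z
        if np.ptp(dist) == 0:
            coph[method] = float("nan")  # correlation undefined (n=2 or equidistant)
            continue
        c, _ = hierarchy.cophenet(Z, dist)
        coph[method] = float(c)
    winner = select_linkage(coph)
    raw = hierarchy.fcluster(trees[winner], t=k, criterion="maxclust")
    return Clustering(
        ids=tuple(df.index),
        labels=_canonical_labels(raw),
        k=int(len(np.unique(raw))),
        method=f"hierarchical+{winner}",
        linkage_matrix=trees[winner],
        cophenetic=coph,
        chosen_linkage=winner,
    )


# ---------------------------------------------------------------------------
# bootstrap stability

@dataclasses.dataclass(frozen=True)
class StabilityResult:
    """Clusterwise bootstrap stability.

    mean_jaccard
        Per original cluster: mean over replicates of the best-match
        Jaccard similarity against the resample clustering.
    dissolution_rate
        Per original cluster: share of replicates with best-match
        Jaccard below 0.5 (the cluster "dissolved").
    n_replicates / n_skipped
        Replicates used / skipped as degenerate (fewer distinct sites
        than clusters requested).
    """

    mean_jaccard: dict[int, float]
    dissolution_rate: dict[int, float]
    n_replicates: int
    n_skipped: int

    @property
    def min_mean_jaccard(self) -> float:
        return min(self.mean_jaccard.values())


def best_match_jaccard(
    original_members: set,
    resample_labels: np.ndarray,
    resample_ids: Sequence,
) -> float:
    """Best Jaccard similarity of one original cluster against every
    cluster of a resample clustering, computed on the original sites
    present in the resample (duplicates collapse to one)."""
    present = set(resample_ids)
    a = original_members & present
    if not a:
        return 0.0
    best = 0.0
    for lab in np.unique(resample_labels):
        b = {i for i, l in zip(resample_ids, resample_labels) if l == lab}
        inter = len(a & b)
        union = len(a | b)
        if union and inter / union > best:
            best = inter / union
    return best


def bootstrap_stability(
    matrix: ConcentrationTable | pd.DataFrame | np.ndarray,
    cluster_fn: Callable[[pd.DataFrame, int], Clustering],
    B: int = 100,
    seed: int = 0,
) -> StabilityResult:
    """Clusterwise bootstrap: resample sites with replacement, recluster,
    and score each original cluster by its best-match Jaccard.

    ``cluster_fn(frame, seed)`` must return a Clustering of the given
    frame; it is called once on the full data and once per replicate.
    Replicates whose resample has too few distinct sites to cluster are
    skipped and counted.
    """
    if B < 1:
        raise ValueError("need B >= 1 bootstrap replicates")
    df = _as_matrix(matrix)
    n = df.shape[0]
    rng = np.random.default_rng(seed)
    base = cluster_fn(df, int(rng.integers(2**31)))
    clusters = {c: base.members(c) for c in range(1, base.k + 1)}

    jaccards: dict[int, list[float]] = {c: [] for c in clusters}
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = df.iloc[idx]
        sub_ids = list(df.index[idx])
        rep_seed = int(rng.integers(2**31))
        if len(set(sub_ids)) < base.k:
            skipped += 1
            continue
        # duplicate rows are kept in the resample fit, as in ordinary
        # bootstrap; the Jaccard match collapses them back to site sets
        sub = sub.set_axis(range(len(sub_ids)), axis=0)
        try:
            rep = cluster_fn(sub, rep_seed)
        except ValueError:
            skipped += 1
            continue
        for c, members in clusters.items():
            jaccards[c].append(best_match_jaccard(members, rep.labels, sub_ids))

    used = B - skipped
    if used == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    return StabilityResult(
        mean_jaccard={c: float(np.mean(v)) for c, v in jaccards.items()},
        dissolution_rate={c: float(np.mean([j < 0.5 for j in v])) for c, v in jaccards.items()},
        n_replicates=used,
        n_skipped=skipped,
    )


def kmeans_recipe(k: int, restarts: int = 25) -> Callable[[pd.DataFrame, int], Clustering]:
    """Clustering recipe for :func:`bootstrap_stability` using k-means."""
    return lambda frame, seed: kmeans_partition(frame, k=k, seed=seed, restarts=restarts)


def hierarchical_recipe(
    k: int, linkages: Sequence[str] = LINKAGE_PREFERENCE
) -> Callable[[pd.DataFrame, int], Clustering]:
    """Clustering recipe for :func:`bootstrap_stability` using the
    cophenetic-selected hierarchical cut (seed unused, kept for the
    recipe signature)."""
    return lambda frame, seed: hierarchical_partition(frame, k=k, linkages=linkages)


# ---------------------------------------------------------------------------
# PCA

@dataclasses.dataclass(frozen=True)
class PCAResult:
    """Principal components of the centered input.

    sdev
        Component standard deviations (singular values / sqrt(n-1)).
    proportion / cumulative
        Variance shares; sum / final entry are exactly 1.
    loadings
        Unit-norm eigenvectors (variables × components), each component
        oriented so its largest-magnitude loading is positive.
    cos2
        Per-variable squared-coordinate share across components (rows
        sum to 1): how well each variable is represented.
    contributions
        Per-variable percentage contribution to each component (columns
        sum to 100 for components with nonzero variance).
    """

    sdev: pd.Series
    proportion: pd.Series
    cumulative: pd.Series
    loadings: pd.DataFrame
    cos2: pd.DataFrame
    contributions: pd.DataFrame
    scores: pd.DataFrame


def pca(matrix: ConcentrationTable | pd.DataFrame | np.ndarray) -> PCAResult:
    """PCA of the centered input via singular-value decomposition.

    Feed z-scored data for correlation-matrix PCA, raw data for
    covariance PCA.  All p components are reported; with fewer
    observations than variables the trailing components carry zero
    variance rather than raising.
    """
    df = _as_matrix(matrix)
    n, p = df.shape
    if n < 2 or p < 2:
        raise ValueError("pca needs at least 2 sites and 2 variables")
    X = df.to_numpy() - df.to_numpy().mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    r = len(s)
    V = np.zeros((p, p))
    V[:, :r] = Vt.T
    sing = np.zeros(p)
    sing[:r] = s
    # orient: largest-|loading| entry of each component positive
    for j in range(p):
        col = V[:, j]
        if col.any():
            lead = np.argmax(np.abs(col))
            if col[lead] < 0:
                V[:, j] = -col
                if j < r:
                    U[:, j] = -U[:, j]
    sdev = sing / np.sqrt(n - 1)
    var = sdev**2
    total = var.sum()
    prop = var / total if total > 0 else np.full(p, np.nan)
    comp = [f"PC{j + 1}" for j in range(p)]
    coords = V * sdev  # variable coordinates (loading * sdev)
    sq = coords**2
    row_tot = sq.sum(axis=1, keepdims=True)
    cos2 = np.divide(sq, row_tot, out=np.zeros_like(sq), where=row_tot > 0)
    col_tot = sq.sum(axis=0, keepdims=True)
    contrib = 100.0 * np.divide(sq, col_tot, out=np.zeros_like(sq), where=col_tot > 0)
    scores = np.zeros((n, p))
    scores[:, :r] = U * s
    return PCAResult(
        sdev=pd.Series(sdev, index=comp),
        proportion=pd.Series(prop, index=comp),
        cumulative=pd.Series(np.cumsum(prop), index=comp),
        loadings=pd.DataFrame(V, index=df.columns, columns=comp),
        cos2=pd.DataFrame(cos2, index=df.columns, columns=comp),
        contributions=pd.DataFrame(contrib, index=df.columns, columns=comp),
        scores=pd.DataFrame(scores, index=df.index, columns=comp),
    )


# ---------------------------------------------------------------------------
# partition comparison

def compare_partitions(a: Clustering, b: Clustering) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index and contingency table of two partitions of the
    same site set (1 iff identical up to relabeling)."""
    if set(a.ids) != set(b.ids):
        raise ValueError("partitions cover different site sets")
    order = list(a.ids)
    b_map = dict(zip(b.ids, b.labels))
    b_labels = np.array([b_map[i] for i in order])
    ari = float(adjusted_rand_score(a.labels, b_labels))
    table = pd.crosstab(pd.Series(a.labels, name="a"), pd.Series(b_labels, name="b"))
    return ari, table
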