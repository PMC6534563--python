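"""Clusters of DVs in the factor-loading embedding.

DVs are clustered not in raw participant space but in the psychological
space defined by their factor loadings. Because measure direction is
arbitrary (an "impulsivity" DV could equally be scored as "self-control"),
the metric is the absolute correlation distance between loading rows,

    d_ij = 1 - |corr(L_i, L_j)|.

An average-linkage tree over this metric is cut with a dynamic hybrid
procedure: branches are detected from the tree shape using core-scatter and
gap criteria (so different branches are effectively cut at different
heights), and leftover objects are attached to the nearest cluster by
average dissimilarity. A single-height cut (optionally silhouette-optimized
over merge heights) is provided for comparison, along with adjusted mutual
information, simulation-based consensus clustering, and 2-D embeddings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_mutual_info_score, silhouette_samples

logger = logging.getLogger(__name__)

UNASSIGNED = 0  # label for objects no cluster claims


class ClusteringError(RuntimeError):
    pass


@dataclass
class DistanceMatrix:
    d: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ClusteringError("distance matrix shape/label mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ClusteringError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ClusteringError("distance matrix diagonal not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-9:
            raise ClusteringError("distances must lie in [0, 1]")
        self.d = np.clip(d, 0.0, 1.0)
        np.fill_diagonal(self.d, 0.0)


@dataclass
class ClusterSolution:
    tree: np.ndarray                    # scipy linkage matrix
    labels: pd.Series | None = None     # per-DV cluster id; 0 = unassigned
    method: str = "tree_only"
    params: dict = field(default_factory=dict)
    dv_names: list[str] = field(default_factory=list)

    def n_clusters(self) -> int:
        if self.labels is None:
            return 0
        return int(len(set(self.labels) - {UNASSIGNED}))


@dataclass
class ConsensusResult:
    cooccurrence: pd.DataFrame
    consensus_labels: pd.Series
    ami_vs_original: float
    within_mean: float
    between_mean: float
    n_sim: int


# -- distance and tree --------------------------------------------------------

def loading_distance(L: pd.DataFrame | np.ndarray, dv_names=None) -> DistanceMatrix:
    """Absolute-correlation distance between DV loading rows."""
    if isinstance(L, pd.DataFrame):
        dv_names = list(L.index)
        L = L.to_numpy(dtype=float)
    elif dv_names is None:
        dv_names = [f"dv{i}" for i in range(np.asarray(L).shape[0])]
    L = np.asarray(L, dtype=float)
    sd = L.std(axis=1)
    const = np.where(sd == 0)[0]
    if len(const):
        raise ClusteringError(
            f"constant loading row(s): {[dv_names[i] for i in const]}"
        )
    C = np.corrcoef(L)
    d = 1.0 - np.abs(np.clip(C, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, dv_names)


def build_tree(dist: DistanceMatrix, linkage_method: str = "average") -> ClusterSolution:
    """Agglomerative merge tree (UPGMA by default) over the distance matrix."""
    if len(dist.labels) < 2:
        raise ClusteringError("need at least 2 DVs to build a tree")
    Z = hierarchy.linkage(squareform(dist.d, checks=False), method=linkage_method)
    return ClusterSolution(
        tree=Z, method="tree_only",
        params={"linkage": linkage_method}, dv_names=list(dist.labels),
    )


# -- dynamic hybrid cut -------------------------------------------------------

def _core_size(branch_size: int, min_cluster_size: int) -> int:
    base = min_cluster_size / 2 + 1
    if base < branch_size:
        return int(base + np.sqrt(branch_size - base))
    return branch_size


def _members(Z: np.ndarray, node: int, m: int, cache: dict) -> list[int]:
    """Leaves under a linkage node, ordered by joining height (earliest first)."""
    if node < m:
        return [node]
    if node in cache:
        return cache[node]
    a, b = int(Z[node - m, 0]), int(Z[node - m, 1])
    res = _members(Z, a, m, cache) + _members(Z, b, m, cache)
    cache[node] = res
    return res


def dynamic_tree_cut(
    solution: ClusterSolution,
    dist: DistanceMatrix,
    min_cluster_size: int = 3,
    deep_split: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = True,
    max_pam_dist: float | None = None,
) -> ClusterSolution:
    """Adaptive-height tree cut (dynamic hybrid variant).

    Stage 1 decomposes the tree top-down: a node is split into its two
    subtrees only when both qualify as distinct branches — each must have at
    least ``min_cluster_size`` members, a compact core (mean pairwise
    distance among its earliest-joined core members below a scatter
    threshold), and a clear gap between the merge height and that core
    scatter. The scatter/gap thresholds come from ``deep_split`` (0-4;
    higher splits more aggressively) expressed relative to the span between
    a low reference height (5th percentile of merge heights) and
    ``cut_height``. Leaf clusters smaller than ``min_cluster_size`` are
    dissolved to unassigned. Stage 2 attaches each unassigned object to the
    cluster with the smallest average dissimilarity, provided that
    dissimilarity is below ``max_pam_dist`` (default: the cut height).
    """
    Z = solution.tree
    m = len(solution.dv_names)
    if min_cluster_size > m:
        raise ClusteringError("min_cluster_size exceeds number of DVs")
    if not 0 <= deep_split <= 4:
        raise ClusteringError("deep_split must be in 0..4")
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    if cut_height is None:
        # the absolute-correlation metric is bounded by 1, so the default cut
        # is absolute; branch gaps are judged against the full metric scale
        cut_height = max(0.99, hmax * 0.99)
    ref_height = float(np.quantile(heights, 0.05))
    span = max(cut_height - ref_height, 1e-12)
    max_core_scatter_frac = [0.64, 0.73, 0.82, 0.91, 0.95][deep_split]
    min_gap_frac = (1.0 - max_core_scatter_frac) * 3.0 / 4.0
    max_abs_core_scatter = ref_height + max_core_scatter_frac * span
    min_abs_gap = min_gap_frac * span

    cache: dict = {}
    D = dist.d

    def core_scatter(node: int) -> float:
        mem = _members(Z, node, m, cache)
        core = mem[: _core_size(len(mem), min_cluster_size)]
        if len(core) < 2:
            return 0.0
        sub = D[np.ix_(core, core)]
        k = len(core)
        return float(sub.sum() / (k * (k - 1)))

    def qualifies(node: int, merge_height: float) -> bool:
        mem = _members(Z, node, m, cache)
        if len(mem) < min_cluster_size:
            return False
        cs = core_scatter(node)
        return cs < max_abs_core_scatter and (merge_height - cs) > min_abs_gap

    # forest of subtrees fully below the cut height
    labels = np.full(m, UNASSIGNED, dtype=int)
    next_label = [1]

    def assign(node: int) -> None:
        mem = _members(Z, node, m, cache)
        if len(mem) >= min_cluster_size:
            labels[mem] = next_label[0]
            next_label[0] += 1

    def split(node: int) -> None:
        if node < m:
            return
        a, b = int(Z[node - m, 0]), int(Z[node - m, 1])
        h = float(Z[node - m, 2])
        if qualifies(a, h) and qualifies(b, h):
            for child in (a, b):
                if child >= m and _splittable(child):
                    split(child)
                else:
                    assign(child)
        else:
            assign(node)

    def _splittable(node: int) -> bool:
        a, b = int(Z[node - m, 0]), int(Z[node - m, 1])
        h = float(Z[node - m, 2])
        return qualifies(a, h) and qualifies(b, h)

    # roots: nodes whose parent is above cut height (or the tree root)
    parent_above = np.zeros(2 * m - 1, dtype=bool)
    for i in range(m - 1):
        if Z[i, 2] > cut_height:
            parent_above[int(Z[i, 0])] = True
            parent_above[int(Z[i, 1])] = True
    roots = [i for i in range(2 * m - 1) if parent_above[i] and
             (i < m or Z[i - m, 2] <= cut_height)]
    if not roots:
        roots = [2 * m - 2]
    for r in roots:
        if r < m:
            continue  # singleton attached above the cut: unassigned
        if _splittable(r):
            split(r)
        else:
            assign(r)

    # stage 2: attach stragglers by average dissimilarity
    if pam_stage:
        if max_pam_dist is None:
            max_pam_dist = cut_height
        cluster_ids = sorted(set(labels) - {UNASSIGNED})
        for i in np.where(labels == UNASSIGNED)[0]:
            best, best_d = UNASSIGNED, np.inf
            for c in cluster_ids:
                mem = np.where(labels == c)[0]
                avg = D[i, mem].mean()
                if avg < best_d:
                    best, best_d = c, avg
            if best != UNASSIGNED and best_d <= max_pam_dist:
                labels[i] = best

    # relabel consecutively in dendrogram order
    mapping, out = {}, np.full(m, UNASSIGNED, dtype=int)
    for i in hierarchy.leaves_list(Z):
        lab = labels[i]
        if lab == UNASSIGNED:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return ClusterSolution(
        tree=Z,
        labels=pd.Series(out, index=solution.dv_names),
        method="dynamic_hybrid",
        params={
            "min_cluster_size": min_cluster_size,
            "deep_split": deep_split,
            "cut_height": cut_height,
            "pam_stage": pam_stage,
        },
        dv_names=list(solution.dv_names),
    )


# -- fixed-height cut ---------------------------------------------------------

def fixed_height_cut(
    solution: ClusterSolution,
    dist: DistanceMatrix,
    height: float | None = None,
    n_clusters: int | None = None,
) -> ClusterSolution:
    """Single-height cut; give either a height or a target cluster count."""
    Z = solution.tree
    if (height is None) == (n_clusters is None):
        raise ClusteringError("give exactly one of height / n_clusters")
    if height is not None:
        if not 0 <= height <= Z[:, 2].max() + 1:
            raise ClusteringError("cut height outside tree range")
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
        params = {"height": float(height)}
    else:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        params = {"n_clusters": int(n_clusters)}
    return ClusterSolution(
        tree=Z,
        labels=pd.Series(labels.astype(int), index=solution.dv_names),
        method="fixed_height",
        params=params,
        dv_names=list(solution.dv_names),
    )


def silhouette_sweep(solution: ClusterSolution, dist: DistanceMatrix) -> dict:
    """Silhouette-vs-height curve over merge heights; returns the best cut."""
    Z = solution.tree
    heights = np.unique(Z[:, 2])
    mids = (heights[:-1] + heights[1:]) / 2.0
    candidates = np.concatenate([mids, [heights[-1] + 1e-9]])
    rows, best = [], None
    for h in candidates:
        labels = hierarchy.fcluster(Z, t=h, criterion="distance")
        k = len(set(labels))
        if k < 2 or k >= len(labels):
            rows.append({"height": h, "n_clusters": k, "mean_silhouette": np.nan})
            continue
        s = float(
            silhouette_samples(dist.d, labels, metric="precomputed").mean()
        )
        rows.append({"height": h, "n_clusters": k, "mean_silhouette": s})
        if best is None or s > best[1]:
            best = (h, s)
    if best is None:
        raise ClusteringError("no height produced 2..m-1 clusters")
    return {
        "curve": pd.DataFrame(rows),
        "best": fixed_height_cut(solution, dist, height=best[0]),
        "best_height": best[0],
        "best_silhouette": best[1],
    }


# -- evaluation ---------------------------------------------------------------

def silhouette(dist: DistanceMatrix, labels: pd.Series | np.ndarray) -> dict:
    """Per-DV silhouette s(i) = (b - a)/max(a, b) and its mean.

    Unassigned DVs (label 0) are excluded from the mean with a warning;
    singleton clusters score 0 by convention.
    """
    lab = np.asarray(labels if not isinstance(labels, pd.Series) else labels.to_numpy())
    mask = lab != UNASSIGNED
    if mask.sum() < len(lab):
        warnings.warn(f"{(~mask).sum()} unassigned DV(s) excluded from silhouette")
    lab_in = lab[mask]
    if len(set(lab_in)) < 2:
        raise ClusteringError("silhouette undefined for a single cluster")
    d_in = dist.d[np.ix_(mask, mask)]
    s = silhouette_samples(d_in, lab_in, metric="precomputed")
    per_dv = np.full(len(lab), np.nan)
    per_dv[mask] = s
    return {
        "per_dv": pd.Series(per_dv, index=dist.labels),
        "mean": float(s.mean()),
    }


def adjusted_mutual_information(labels_a, labels_b) -> float:
    """AMI with arithmetic-mean normalization and hypergeometric E[MI]."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ClusteringError("partition length mismatch")
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


# -- consensus robustness -----------------------------------------------------

def consensus_cluster(
    loading_mean: pd.DataFrame,
    loading_sd: pd.DataFrame,
    original_labels: pd.Series,
    n_sim: int = 5000,
    drop_frac: float = 0.2,
    seed: int | None = 0,
    min_cluster_size: int = 3,
    deep_split: int = 2,
    linkage_method: str = "average",
) -> ConsensusResult:
    """Stability of the clustering under loading noise and DV dropout.

    Each simulation draws every loading element from Normal(mean, sd)
    (moments from the bootstrap), drops ``drop_frac`` of DVs at random, and
    reruns distance -> tree -> dynamic cut. Pairwise co-occurrence is the
    fraction of simulations, among those retaining both DVs, where they
    landed in the same cluster; 1 - co-occurrence is then clustered by the
    identical pipeline to give the consensus solution.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives a noisy co-occurrence estimate")
    rng = np.random.default_rng(seed)
    names = list(loading_mean.index)
    m = len(names)
    mu = loading_mean.to_numpy(dtype=float)
    sd = loading_sd.to_numpy(dtype=float)
    together = np.zeros((m, m))
    joint = np.zeros((m, m))
    n_keep = max(int(round((1.0 - drop_frac) * m)), min_cluster_size + 1)
    failures = 0
    for _ in range(n_sim):
        Lsim = rng.normal(mu, sd)
        keep = np.sort(rng.choice(m, size=n_keep, replace=False))
        try:
            dist = loading_distance(Lsim[keep], [names[i] for i in keep])
            tree = build_tree(dist, linkage_method)
            cut = dynamic_tree_cut(
                tree, dist, min_cluster_size=min_cluster_size, deep_split=deep_split
            )
        except (ClusteringError, ValueError):
            failures += 1
            continue
        lab = cut.labels.to_numpy()
        sub = np.ix_(keep, keep)
        joint[sub] += 1
        assigned = lab != UNASSIGNED
        same = (lab[:, None] == lab[None, :]) & assigned[:, None] & assigned[None, :]
        idx = np.ix_(keep, keep)
        together[idx] += same
    if failures > 0.05 * n_sim:
        raise ClusteringError(f"{failures}/{n_sim} simulations failed")
    with np.errstate(invalid="ignore", divide="ignore"):
        co = np.where(joint > 0, together / joint, 0.0)
    np.fill_diagonal(co, 1.0)
    co = (co + co.T) / 2.0
    cons_dist = DistanceMatrix(np.clip(1.0 - co, 0.0, 1.0), names)
    cons_tree = build_tree(cons_dist, linkage_method)
    cons = dynamic_tree_cut(
        cons_tree, cons_dist, min_cluster_size=min_cluster_size, deep_split=deep_split
    )
    ami = adjusted_mutual_information(
        original_labels.loc[names].to_numpy(), cons.labels.to_numpy()
    )
    orig = original_labels.loc[names].to_numpy()
    offdiag = ~np.eye(m, dtype=bool)
    same_orig = (orig[:, None] == orig[None, :]) & (orig[:, None] != UNASSIGNED)
    within = co[same_orig & offdiag]
    between = co[(~same_orig) & offdiag]
    return ConsensusResult(
        cooccurrence=pd.DataFrame(co, index=names, columns=names),
        consensus_labels=cons.labels,
        ami_vs_original=ami,
        within_mean=float(within.mean()) if within.size else np.nan,
        between_mean=float(between.mean()) if between.size else np.nan,
        n_sim=n_sim - failures,
    )


# -- 2-D embeddings -----------------------------------------------------------

def embed_2d(
    data: DistanceMatrix | np.ndarray,
    method: str = "mds",
    seed: int | None = 0,
    n_init: int = 4,
) -> dict:
    """Metric MDS of a distance matrix, or PCA of a score/loading matrix."""
    if method == "mds":
        from sklearn.manifold import MDS

        if not isinstance(data, DistanceMatrix):
            raise ClusteringError("MDS embedding needs a DistanceMatrix")
        if len(data.labels) < 3:
            raise ClusteringError("need at least 3 points to embed")
        mds = MDS(
            n_components=2, metric="precomputed", random_state=seed,
            init="random", n_init=n_init, normalized_stress=False,
        )
        coords = mds.fit_transform(data.d)
        return {"coords": pd.DataFrame(coords, index=data.labels,
                                       columns=["dim1", "dim2"]),
                "stress": float(mds.stress_)}
    if method == "pca":
        from sklearn.decomposition import PCA

        X = np.asarray(data, dtype=float)
        if X.shape[0] < 3:
            raise ClusteringError("need at least 3 points to embed")
        pca = PCA(n_components=2)
        coords = pca.fit_transform(X)
        return {"coords": pd.DataFrame(coords, columns=["dim1", "dim2"]),
                "variance_explained": pca.explained_variance_ratio_}
    raise ClusteringError(f"unknown embedding method {method!r}")
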