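"""Two-step cluster analysis with automatic cluster-number selection.

The procedure follows the classic scalable two-step design: (1) a sequential
CF-tree pass compresses the sample into pre-clusters held as sufficient
statistics (count, linear sum, square sum); (2) the pre-clusters are merged
agglomeratively under Euclidean centroid distance, a likelihood-based BIC is
recorded for every partition along the way, and the number of clusters is
chosen by a two-stage rule combining BIC change ratios with merge-distance
ratios.  Cluster quality is summarised by the mean silhouette coefficient.

At study scale (a few hundred subjects) the tree adds nothing, so
``bypass_tree=True`` — every subject its own pre-cluster — is the default and
makes the procedure exactly deterministic agglomerative clustering; the
CF-tree path exists for large-N use and is insertion-order dependent, as is
inherent to the sequential pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .scoring import CompositeScoreMatrix


class ClusteringError(ValueError):
    pass


# --------------------------------------------------------------------------
# pre-clusters and the CF-tree

@dataclass
class PreCluster:
    """Sufficient statistics of a group of points (clustering feature)."""

    n: int
    linear_sum: np.ndarray
    square_sum: np.ndarray
    member_ids: list[int]

    @classmethod
    def from_point(cls, x: np.ndarray, idx: int) -> "PreCluster":
        x = np.asarray(x, dtype=float)
        return cls(1, x.copy(), x * x, [idx])

    @property
    def centroid(self) -> np.ndarray:
        return self.linear_sum / self.n

    def absorb(self, other: "PreCluster") -> None:
        self.n += other.n
        self.linear_sum = self.linear_sum + other.linear_sum
        self.square_sum = self.square_sum + other.square_sum
        self.member_ids.extend(other.member_ids)

    def merged(self, other: "PreCluster") -> "PreCluster":
        return PreCluster(self.n + other.n,
                          self.linear_sum + other.linear_sum,
                          self.square_sum + other.square_sum,
                          self.member_ids + other.member_ids)


@dataclass(frozen=True)
class CFTreeParams:
    branching_factor: int = 8
    max_leaf_entries: int = 8
    max_depth: int = 3
    initial_threshold: float = 0.0
    bypass_tree: bool = True

    def __post_init__(self):
        if min(self.branching_factor, self.max_leaf_entries, self.max_depth) < 2:
            raise ClusteringError("CF-tree parameters must be >= 2")
        if self.initial_threshold < 0:
            raise ClusteringError("initial_threshold must be >= 0")


class _Node:
    __slots__ = ("is_leaf", "entries")

    def __init__(self, is_leaf: bool):
        self.is_leaf = is_leaf
        self.entries: list = []  # leaf: PreCluster; internal: _Node

    def centroids(self) -> np.ndarray:
        if self.is_leaf:
            return np.array([e.centroid for e in self.entries])
        return np.array([e.cf_centroid() for e in self.entries])

    def cf_centroid(self) -> np.ndarray:
        if self.is_leaf:
            n = sum(e.n for e in self.entries)
            s = sum((e.linear_sum for e in self.entries), 0.0)
        else:
            parts = [(c.cf_centroid(), c.cf_n()) for c in self.entries]
            n = sum(p[1] for p in parts)
            s = sum(c * m for c, m in parts)
        return s / n

    def cf_n(self) -> int:
        if self.is_leaf:
            return sum(e.n for e in self.entries)
        return sum(c.cf_n() for c in self.entries)

    def leaf_preclusters(self) -> list[PreCluster]:
        if self.is_leaf:
            return list(self.entries)
        return [pc for child in self.entries for pc in child.leaf_preclusters()]


def _split(node: _Node, branching: int) -> tuple[_Node, _Node]:
    """Split an overfull node by farthest-pair seeding."""
    cents = node.centroids()
    i, j = max(itertools.combinations(range(len(cents)), 2),
               key=lambda ij: float(np.sum((cents[ij[0]] - cents[ij[1]]) ** 2)))
    left, right = _Node(node.is_leaf), _Node(node.is_leaf)
    for k, entry in enumerate(node.entries):
        di = np.sum((cents[k] - cents[i]) ** 2)
        dj = np.sum((cents[k] - cents[j]) ** 2)
        (left if di <= dj else right).entries.append(entry)
    return left, right


class _RebuildNeeded(Exception):
    pass


class _CFTree:
    def __init__(self, params: CFTreeParams, threshold: float):
        self.params = params
        self.threshold = threshold
        self.root = _Node(is_leaf=True)
        self.depth = 1

    def insert(self, pc: PreCluster) -> None:
        split = self._insert_into(self.root, pc)
        if split is not None:
            if self.depth + 1 > self.params.max_depth:
                raise _RebuildNeeded
            new_root = _Node(is_leaf=False)
            new_root.entries = list(split)
            self.root = new_root
            self.depth += 1

    def _insert_into(self, node: _Node, pc: PreCluster):
        if node.is_leaf:
            if node.entries:
                cents = node.centroids()
                d = np.sqrt(np.sum((cents - pc.centroid) ** 2, axis=1))
                best = int(np.argmin(d))
                if d[best] <= self.threshold:
                    node.entries[best].absorb(pc)
                    return None
            node.entries.append(pc)
            if len(node.entries) > self.params.max_leaf_entries:
                return _split(node, self.params.branching_factor)
            return None
        cents = node.centroids()
        d = np.sum((cents - pc.centroid) ** 2, axis=1)
        child = node.entries[int(np.argmin(d))]
        split = self._insert_into(child, pc)
        if split is not None:
            node.entries.remove(child)
            node.entries.extend(split)
            if len(node.entries) > self.params.branching_factor:
                return _split(node, self.params.branching_factor)
        return None

    def min_inter_entry_distance(self) -> float:
        pcs = self.root.leaf_preclusters()
        cents = np.array([p.centroid for p in pcs])
        d = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min())


def build_cf_tree(scores: CompositeScoreMatrix | np.ndarray,
                  params: CFTreeParams | None = None,
                  order: np.ndarray | None = None) -> list[PreCluster]:
    """Step one: compress the sample into pre-clusters.

    Points are inserted sequentially (input row order by default; pass *order*
    for a sensitivity shuffle): each descends to the closest leaf entry by
    Euclidean centroid distance and is absorbed if within the threshold, else
    opens a new entry.  When the tree outgrows its capacity it is rebuilt with
    the threshold raised to the smallest inter-entry distance observed, which
    monotonically coarsens the pre-clustering.  With ``bypass_tree=True``
    every point becomes its own singleton pre-cluster.
    """
    X = scores.values if isinstance(scores, CompositeScoreMatrix) else np.asarray(scores, float)
    if X.ndim != 2 or len(X) < 2:
        raise ClusteringError("need an N x d matrix with N >= 2")
    if np.isnan(X).any():
        raise ClusteringError("scores contain NaN")
    params = params or CFTreeParams()
    idx = np.arange(len(X)) if order is None else np.asarray(order)
    if params.bypass_tree:
        return [PreCluster.from_point(X[i], int(i)) for i in idx]

    tree = _CFTree(params, params.initial_threshold)
    for i in idx:
        try:
            tree.insert(PreCluster.from_point(X[i], int(i)))
        except _RebuildNeeded:
            # the point is already among the (overfull) root's leaf entries;
            # rebuild from those with an escalated threshold
            tree = _rebuild(tree, params)
    return tree.root.leaf_preclusters()


def _rebuild(tree: _CFTree, params: CFTreeParams) -> _CFTree:
    entries = tree.root.leaf_preclusters()
    threshold = tree.threshold
    while True:
        new_threshold = tree.min_inter_entry_distance()
        if not new_threshold > threshold:
            new_threshold = max(threshold * 2.0, 1e-12)
        threshold = new_threshold
        tree = _CFTree(params, threshold)
        failed_at = None
        for pos, pc in enumerate(entries):
            try:
                tree.insert(pc)
            except _RebuildNeeded:
                failed_at = pos
                break
        if failed_at is None:
            return tree
        # the colliding entry is already among the tree's leaves; carry over
        # what the tree holds plus the not-yet-reinserted remainder
        entries = tree.root.leaf_preclusters() + entries[failed_at + 1:]


# --------------------------------------------------------------------------
# step two: agglomeration, BIC, auto-k

@dataclass
class MergeDendrogram:
    """Record of the centroid-linkage agglomeration over pre-clusters."""

    n_preclusters: int
    n_subjects: int
    merges: list[tuple[int, int, float]]        # (index kept, index removed, distance)
    partitions: dict[int, np.ndarray]           # k -> precluster -> cluster label (0-based)
    bic: dict[int, float]                       # k -> BIC of that partition
    merge_distance: dict[int, float]            # k -> distance of the k -> k-1 merge


def _bic_from_stats(ns, lss, sss, cohort_var, n_total, var_floor_rel=1e-9):
    """BIC of a partition from per-cluster sufficient statistics.

    BIC(J) = -2 sum_j xi_j + 2 d J log N, with
    xi_j = -N_j * sum_v 0.5 * log(cohort_var_v + within_var_jv); the within
    variance is floored at ``var_floor_rel * cohort_var_v`` to guard log(0)
    for single-member or degenerate clusters.
    """
    d = len(cohort_var)
    # absolute floor keeps constant (zero-variance) dimensions finite; they
    # then contribute the same constant to every partition's BIC
    cohort_var = np.maximum(cohort_var, 1e-12 * max(1.0, float(cohort_var.max())))
    floor = var_floor_rel * cohort_var
    xi_total = 0.0
    for n, ls, ss in zip(ns, lss, sss):
        mu = ls / n
        within = np.maximum(ss / n - mu * mu, floor)
        xi_total += -n * 0.5 * np.log(cohort_var + within).sum()
    return -2.0 * xi_total + 2.0 * d * len(ns) * np.log(n_total)


def bic(partition: list[list[int]], X: np.ndarray) -> float:
    """BIC of an explicit partition of the rows of *X* (point-level API)."""
    X = np.asarray(X, dtype=float)
    n_total = len(X)
    if sorted(i for part in partition for i in part) != list(range(n_total)):
        raise ClusteringError("partition must cover all subjects exactly once")
    if any(len(p) == 0 for p in partition):
        raise ClusteringError("empty cluster in partition")
    cohort_var = X.var(axis=0)
    ns = [len(p) for p in partition]
    lss = [X[p].sum(axis=0) for p in partition]
    sss = [(X[p] ** 2).sum(axis=0) for p in partition]
    return _bic_from_stats(ns, lss, sss, cohort_var, n_total)


def agglomerate(preclusters: list[PreCluster],
                X: np.ndarray | CompositeScoreMatrix | None = None) -> MergeDendrogram:
    """Merge pre-clusters bottom-up under Euclidean centroid distance.

    At every step the pair of clusters with minimum centroid distance is
    merged (ties broken by the lowest index pair); merged sufficient
    statistics are exact sums.  Records the partition, its BIC, and the merge
    distance for every cluster count from the initial pre-cluster count down
    to 1.  *X* (the point matrix) is only needed to compute the cohort
    variance exactly when pre-clusters hide within-pre-cluster spread; it is
    reconstructed from the sufficient statistics otherwise.
    """
    P = len(preclusters)
    if P < 2:
        raise ClusteringError("need at least 2 pre-clusters")
    n_total = sum(pc.n for pc in preclusters)

    if X is not None:
        pts = X.values if isinstance(X, CompositeScoreMatrix) else np.asarray(X, float)
        cohort_var = pts.var(axis=0)
    else:
        ls = sum((pc.linear_sum for pc in preclusters), 0.0)
        ss = sum((pc.square_sum for pc in preclusters), 0.0)
        cohort_var = ss / n_total - (ls / n_total) ** 2

    ns = np.array([pc.n for pc in preclusters], dtype=float)
    lss = np.array([pc.linear_sum for pc in preclusters])
    sss = np.array([pc.square_sum for pc in preclusters])
    active = np.ones(P, dtype=bool)
    labels = np.arange(P)

    cents = lss / ns[:, None]
    D = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
    iu = np.tril_indices(P)
    D[iu] = np.inf  # keep only i < j; row-major argmin = lexicographic tie-break

    partitions = {P: labels.copy()}
    bics = {}
    merge_distance = {}
    merges = []

    act = active.nonzero()[0]
    bics[P] = _bic_from_stats(ns[act], lss[act], sss[act], cohort_var, n_total)

    k = P
    while k > 1:
        i, j = np.unravel_index(np.argmin(D), D.shape)
        dist = float(D[i, j])
        merges.append((int(i), int(j), dist))
        merge_distance[k] = dist
        ns[i] += ns[j]
        lss[i] += lss[j]
        sss[i] += sss[j]
        active[j] = False
        labels[labels == j] = i
        D[j, :] = np.inf
        D[:, j] = np.inf
        ci = lss[i] / ns[i]
        others = active.nonzero()[0]
        dvec = np.sqrt(((lss[others] / ns[others, None] - ci) ** 2).sum(-1))
        for o, dv in zip(others, dvec):
            if o == i:
                continue
            a, b = (i, o) if i < o else (o, i)
            D[a, b] = dv
        k -= 1
        # relabel to contiguous 0..k-1 in order of first appearance
        part = np.zeros(P, dtype=int)
        seen = {}
        for p in range(P):
            root = labels[p]
            if root not in seen:
                seen[root] = len(seen)
            part[p] = seen[root]
        partitions[k] = part
        act = active.nonzero()[0]
        bics[k] = _bic_from_stats(ns[act], lss[act], sss[act], cohort_var, n_total)

    return MergeDendrogram(n_preclusters=P, n_subjects=n_total, merges=merges,
                           partitions=partitions, bic=bics,
                           merge_distance=merge_distance)


@dataclass
class SelectionDiagnostics:
    coarse_k: int
    bic_change_ratios: dict[int, float]
    distance_ratios: dict[int, float]


def select_cluster_count(dendrogram: MergeDendrogram,
                         c1: float = 0.04, c2: float = 1.15,
                         k_max: int = 15) -> tuple[int, SelectionDiagnostics]:
    """Two-stage automatic choice of the number of clusters.

    Stage 1 walks the BIC trace: with dBIC(k) = BIC(k) - BIC(k+1), the coarse
    estimate is the smallest k whose change ratio dBIC(k)/dBIC(1) drops below
    *c1* (if the BIC does not improve from 1 to 2 clusters at all, k = 1).
    Stage 2 refines within k <= coarse using merge-distance ratios
    R(k) = d(k -> k-1) / d(k+1 -> k): if the largest ratio dominates the
    second largest by more than *c2* its k wins, otherwise the larger of the
    two candidate k is taken.
    """
    if k_max < 2:
        raise ClusteringError("k_max must be >= 2")
    k_hi = min(k_max, dendrogram.n_preclusters - 1)
    if k_hi < 2 or 2 not in dendrogram.bic:
        return 1, SelectionDiagnostics(1, {}, {})
    bic_t = dendrogram.bic
    d1 = bic_t[1] - bic_t[2]
    ratios = {k: (bic_t[k] - bic_t[k + 1]) / d1 for k in range(1, k_hi + 1)
              if k + 1 in bic_t} if d1 > 0 else {}
    if d1 <= 0:
        return 1, SelectionDiagnostics(1, {}, {})
    coarse = k_hi
    for k in sorted(ratios):
        if ratios[k] < c1:
            coarse = k
            break
    if coarse == 1:
        return 1, SelectionDiagnostics(1, ratios, {})

    md = dendrogram.merge_distance
    dist_ratios = {}
    for k in range(2, coarse + 1):
        if k in md and (k + 1) in md and md[k + 1] > 0:
            dist_ratios[k] = md[k] / md[k + 1]
    if not dist_ratios:
        return coarse, SelectionDiagnostics(coarse, ratios, {})
    ranked = sorted(dist_ratios, key=lambda k: (-dist_ratios[k], k))
    if len(ranked) == 1:
        k_sel = ranked[0]
    else:
        r1, r2 = dist_ratios[ranked[0]], dist_ratios[ranked[1]]
        k_sel = ranked[0] if (r2 == 0 or r1 / r2 > c2) else max(ranked[0], ranked[1])
    return k_sel, SelectionDiagnostics(coarse, ratios, dist_ratios)


# --------------------------------------------------------------------------
# final assignment and quality

@dataclass
class ClusterSolution:
    k_selected: int
    assignments: np.ndarray           # subject -> label in 1..k; cluster 1 = smallest
    centroids: np.ndarray             # k x d
    cluster_sizes: np.ndarray
    mean_silhouette: float
    bic_table: dict[int, float]
    diagnostics: SelectionDiagnostics
    subject_ids: list | None = None

    @property
    def sizes_percent(self) -> np.ndarray:
        return 100.0 * self.cluster_sizes / self.cluster_sizes.sum()


def assign_clusters(scores: CompositeScoreMatrix | np.ndarray,
                    preclusters: list[PreCluster],
                    dendrogram: MergeDendrogram,
                    k: int,
                    diagnostics: SelectionDiagnostics | None = None,
                    refine: bool = False) -> ClusterSolution:
    """Materialise the k-cluster partition as per-subject assignments.

    Subjects inherit the cluster of their pre-cluster.  Labels are renumbered
    1..k with cluster 1 the smallest (ties by original label order), mirroring
    the convention that the minority subtype is reported first.  The optional
    refinement pass (off by default) reassigns each subject to the nearest
    final centroid.
    """
    if isinstance(scores, CompositeScoreMatrix):
        X, ids = scores.values, scores.subject_ids
    else:
        X, ids = np.asarray(scores, float), None
    part = dendrogram.partitions[k]
    raw = np.empty(len(X), dtype=int)
    for p_idx, pc in enumerate(preclusters):
        raw[pc.member_ids] = part[p_idx]

    if refine and k >= 2:
        cents = np.array([X[raw == c].mean(axis=0) for c in range(k)])
        raw = np.argmin(((X[:, None, :] - cents[None, :, :]) ** 2).sum(-1), axis=1)

    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(sizes, kind="stable")      # smallest first
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = relabel[raw]
    sizes = np.bincount(assignments - 1, minlength=k)
    centroids = np.array([X[assignments == c + 1].mean(axis=0) for c in range(k)])
    sil = mean_silhouette(X, assignments) if k >= 2 else float("nan")
    return ClusterSolution(
        k_selected=k, assignments=assignments, centroids=centroids,
        cluster_sizes=sizes, mean_silhouette=sil, bic_table=dict(dendrogram.bic),
        diagnostics=diagnostics or SelectionDiagnostics(k, {}, {}),
        subject_ids=ids,
    )


def mean_silhouette(X: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient under Euclidean distance.

    s(i) = (b - a) / max(a, b) with a the mean distance to the own cluster
    and b the smallest mean distance to another cluster; members of singleton
    clusters contribute s = 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ClusteringError("silhouette requires at least 2 clusters")
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    n = len(X)
    s = np.zeros(n)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        own = D[i, labels == c].sum() / (sizes[c] - 1)
        other = min(D[i, labels == o].mean() for o in uniq if o != c)
        s[i] = (other - own) / max(own, other)
    return float(s.mean())


def cluster_scores(scores: CompositeScoreMatrix | np.ndarray,
                   params: CFTreeParams | None = None,
                   c1: float = 0.04, c2: float = 1.15, k_max: int = 15,
                   k_fixed: int | None = None,
                   refine: bool = False) -> ClusterSolution:
    """Run the full two-step procedure: tree, agglomeration, auto-k, assign."""
    params = params or CFTreeParams()
    pcs = build_cf_tree(scores, params)
    dend = agglomerate(pcs, scores)
    if k_fixed is not None:
        k, diag = k_fixed, SelectionDiagnostics(k_fixed, {}, {})
    else:
        k, diag = select_cluster_count(dend, c1=c1, c2=c2, k_max=k_max)
    return assign_clusters(scores, pcs, dend, k, diag, refine=refine)
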