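"""Discovery of reproducible foraging modules.

Pipeline: prune redundant measures by a correlation-threshold sweep, cluster
excursions with Ward's minimum-variance method (Ward.D2 on Euclidean
distances), cut the dendrogram with an adaptive hybrid tree cut, check that
the data carry more structure than column-shuffled data (cluster-count null),
split into a balanced train/test partition, test each training cluster's
reproducibility with a distance-based in-group-proportion (IGP) permutation
test, control FDR with q-values, and annotate every excursion with its
nearest significant module centroid.

The hybrid tree cut here is an adaptive branch decomposition: walking the
merge sequence bottom-up, two merging branches are locked in as separate
clusters when each is large enough (``min_cluster_size``), separates cleanly
from the join (relative height gap), and is internally tight (scatter
relative to the tree height).  The ``deep_split`` sensitivity (0-4) relaxes
the gap/scatter thresholds, so higher values cut far more aggressively —
notably on unstructured data, which shreds into many minimum-size clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist

from .fdr import estimate_pi0, qvalues

__all__ = [
    "greedy_decorrelate",
    "cluster_ward",
    "cut_tree_hybrid",
    "sweep_thresholds",
    "null_cluster_count_test",
    "partition_balanced",
    "compute_centroids",
    "igp",
    "igp_permutation_test",
    "assign_modules",
    "discover_modules",
    "SelectionSweep",
    "ModuleSet",
    "qvalues",
    "estimate_pi0",
]

# deep_split -> (minimum relative gap, maximum relative scatter,
#                minimum join prominence as a fraction of the cut height)
_DEEP_SPLIT_PARAMS = {
    0: (0.60, 0.40, 0.70),
    1: (0.45, 0.55, 0.55),
    2: (0.30, 0.70, 0.40),
    3: (0.15, 0.85, 0.30),
    4: (0.05, 0.95, 0.20),
}


# --- measure selection ------------------------------------------------------

def greedy_decorrelate(corr: pd.DataFrame, cutoff: float) -> list[str]:
    """Prune measures until no retained pair correlates above ``cutoff``.

    While any off-diagonal |r| > cutoff remains, take the most correlated
    pair and drop the member with the larger mean absolute correlation to
    the other retained measures (ties keep the earlier column).
    """
    if isinstance(corr, pd.DataFrame):
        names = list(corr.columns)
        c = corr.to_numpy(dtype=float)
    else:
        c = np.asarray(corr, dtype=float)
        names = list(range(c.shape[0]))
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    a = np.abs(c.copy())
    np.fill_diagonal(a, 0.0)
    keep = list(range(a.shape[0]))
    while len(keep) > 1:
        sub = a[np.ix_(keep, keep)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        # drop the larger mean |r|; on a tie keep the earlier column
        drop = j if (mean_j > mean_i or (mean_j == mean_i and j > i)) else i
        keep.pop(drop)
    return [names[k] for k in keep]


# --- clustering -------------------------------------------------------------

def cluster_ward(data) -> np.ndarray:
    """Ward.D2 agglomerative dendrogram (scipy linkage) on Euclidean distances."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("clustering requires at least 2 rows")
    return linkage(X, method="ward")


def cut_tree_hybrid(dendrogram: np.ndarray, data=None,
                    deep_split: int = 4, min_cluster_size: int = 20) -> np.ndarray:
    """Adaptive hybrid cut of a dendrogram into clusters (0 = unassigned).

    Walks merges bottom-up; when two branches of size >= ``min_cluster_size``
    join, each branch with relative gap (join height minus branch height,
    over join height) above the ``deep_split`` threshold and relative scatter
    (mean internal merge height over 0.99 x tree height) below it is locked
    in as a cluster.  If no branch ever locks, the whole data set forms one
    cluster (provided it meets ``min_cluster_size``); points never locked are
    left unassigned.  ``min_cluster_size > n`` yields all-unassigned.
    """
    Z = np.asarray(dendrogram, dtype=float)
    n = Z.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    if min_cluster_size > n:
        return labels
    if deep_split not in _DEEP_SPLIT_PARAMS:
        raise ValueError("deep_split must be an integer in 0..4")
    min_gap, max_scatter, min_join = _DEEP_SPLIT_PARAMS[deep_split]
    cut_height = 0.99 * Z[-1, 2] if Z[-1, 2] > 0 else 1.0

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    height = np.zeros(2 * n - 1)
    scatter_sum = np.zeros(2 * n - 1)  # sum of internal merge heights
    scatter_n = np.zeros(2 * n - 1)
    has_locked = np.zeros(2 * n - 1, dtype=bool)
    next_label = 1

    def qualifies(node: int, h_join: float) -> bool:
        if has_locked[node] or len(members[node]) < min_cluster_size:
            return False
        if h_join < min_join * cut_height:
            return False  # join is not prominent: still inside a branch
        gap_rel = (h_join - height[node]) / h_join if h_join > 0 else 0.0
        mean_scatter = (scatter_sum[node] / scatter_n[node]
                        if scatter_n[node] else 0.0)
        return gap_rel >= min_gap and mean_scatter / cut_height <= max_scatter

    for k, (ia, ib, h, _size) in enumerate(Z):
        a, b = int(ia), int(ib)
        node = n + k
        for branch in (a, b):
            if qualifies(branch, h):
                labels[members[branch]] = next_label
                has_locked[branch] = True
                next_label += 1
        has_locked[node] = has_locked[a] or has_locked[b]
        members[node] = members[a] + members[b]
        del members[a], members[b]
        height[node] = h
        scatter_sum[node] = scatter_sum[a] + scatter_sum[b] + h
        scatter_n[node] = scatter_n[a] + scatter_n[b] + 1

    if next_label == 1:
        return np.ones(n, dtype=int)  # no split found: one cluster

    # renumber by decreasing size (stable for ties)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    out = np.zeros(n, dtype=int)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


@dataclass
class SelectionSweep:
    """Correlation-threshold sweep record."""

    entries: list  # (threshold, retained names, cluster count)
    selected_threshold: float
    selected_measures: list


def sweep_thresholds(data: pd.DataFrame, grid=None, deep_split: int = 4,
                     min_cluster_size: int = 20) -> SelectionSweep:
    """Sweep correlation cutoffs; select the one maximizing cluster count.

    Ties prefer the larger cutoff (least pruning).  Grid defaults to
    r = 0.50 ... 0.95 in 0.05 steps.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.951, 0.05), 2)
    grid = [float(g) for g in grid]
    if any(not 0 < g <= 1 for g in grid):
        raise ValueError("grid values must lie in (0, 1]")
    # constant (zero-variance) columns have undefined correlations; they
    # carry no distance information, so treat them as uncorrelated
    corr = data.corr().fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    entries = []
    for r in grid:
        retained = greedy_decorrelate(corr, r)
        if not retained:
            entries.append((r, [], 0))
            continue
        Z = cluster_ward(data[retained].to_numpy())
        labels = cut_tree_hybrid(Z, deep_split=deep_split,
                                 min_cluster_size=min_cluster_size)
        entries.append((r, retained, int(labels.max())))
    best = max(entries, key=lambda e: (e[2], e[0]))
    return SelectionSweep(entries=entries, selected_threshold=best[0],
                          selected_measures=list(best[1]))


def null_cluster_count_test(data: pd.DataFrame, iterations: int = 10_000,
                            seed=None, deep_split: int = 4,
                            min_cluster_size: int = 20):
    """Lower-tailed shuffled-matrix null for the observed cluster count.

    Each iteration permutes values independently within each column (keeping
    the marginals, destroying joint structure), re-clusters, and counts
    clusters.  Structured data yields *fewer* clusters than shuffled data,
    so p = (1 + #{null <= observed}) / (iterations + 1).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)

    def count(mat):
        labels = cut_tree_hybrid(cluster_ward(mat), deep_split=deep_split,
                                 min_cluster_size=min_cluster_size)
        return int(labels.max())

    observed = count(X)
    null_counts = np.empty(iterations, dtype=int)
    shuffled = X.copy()
    for it in range(iterations):
        for j in range(shuffled.shape[1]):
            shuffled[:, j] = X[rng.permutation(X.shape[0]), j]
        null_counts[it] = count(shuffled)
    p = (1 + int((null_counts <= observed).sum())) / (iterations + 1)
    return observed, null_counts, p


# --- train/test partition and IGP ------------------------------------------

def partition_balanced(metadata: pd.DataFrame, strata, fraction: float = 0.5,
                       seed=None):
    """Balanced train/test split within each stratum of the given factors.

    Within each cross-classification cell, round(fraction * size) rows
    (round-half-up) go to train.  Returns (train_index, test_index).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, group in metadata.groupby(list(strata), sort=True, dropna=False):
        idx = group.index.to_numpy()
        if len(idx) == 0:
            continue
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(fraction * len(idx) + 0.5))
        train.extend(idx[perm[:n_train]])
        test.extend(idx[perm[n_train:]])
    return train, test


def compute_centroids(labels: np.ndarray, data: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean measure vectors (rows indexed by cluster id)."""
    labels = np.asarray(labels)
    ids = sorted(set(labels[labels > 0]))
    if not ids:
        raise ValueError("no non-empty clusters")
    X = data.to_numpy(dtype=float)
    rows = {k: X[labels == k].mean(axis=0) for k in ids}
    for k, v in rows.items():
        if np.isnan(v).any():
            raise ValueError(f"cluster {k} is empty")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(data.columns))


def _nearest_neighbor_index(X: np.ndarray) -> np.ndarray:
    """Index of each point's nearest other point (ties -> lowest index)."""
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    return d.argmin(axis=1)


def _assign_to_centroids(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels (0-based; ties -> lowest centroid index)."""
    return cdist(X, C).argmin(axis=1)


def igp(test_data, centroids) -> np.ndarray:
    """In-group proportion of each cluster on the test partition.

    Each test point goes to its nearest centroid (Euclidean); the IGP of
    cluster k is the fraction of its points whose nearest test-set neighbor
    is also assigned to k.  Clusters with < 2 assigned points score 0.
    """
    X = np.asarray(test_data.data if hasattr(test_data, "data") else test_data, float)
    C = np.asarray(centroids, dtype=float)
    if X.shape[1] != C.shape[1]:
        raise ValueError("test data and centroids differ in measure dimension")
    assign = _assign_to_centroids(X, C)
    nn = _nearest_neighbor_index(X)
    return _igp_from_assignment(assign, nn, C.shape[0])


def _igp_from_assignment(assign, nn, k):
    out = np.zeros(k)
    for c in range(k):
        mask = assign == c
        if mask.sum() < 2:
            continue
        out[c] = float((assign[nn[mask]] == c).mean())
    return out


def igp_permutation_test(test_data, centroids, nperm: int = 10_000, seed=None):
    """Distance-based IGP permutation test per cluster.

    The null destroys the test data's joint structure while preserving every
    measure's marginal distribution: each permutation shuffles the test
    matrix independently within each column, reassigns the shuffled points
    to the (fixed) centroids, and recomputes each cluster's IGP with nearest
    neighbors taken in the shuffled data.  A reproducible cluster's observed
    IGP exceeds what its centroid attracts from structureless data.
    p_k = (1 + #{null IGP_k >= observed_k}) / (nperm + 1).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(test_data.data if hasattr(test_data, "data") else test_data, float)
    C = np.asarray(centroids, dtype=float)
    k = C.shape[0]
    nn = _nearest_neighbor_index(X)
    observed = _igp_from_assignment(_assign_to_centroids(X, C), nn, k)
    exceed = np.zeros(k)
    S = np.empty_like(X)
    n = X.shape[0]
    for _ in range(nperm):
        for j in range(X.shape[1]):
            S[:, j] = X[rng.permutation(n), j]
        null_igp = _igp_from_assignment(
            _assign_to_centroids(S, C), _nearest_neighbor_index(S), k)
        exceed += null_igp >= observed
    pvals = (1 + exceed) / (nperm + 1)
    return observed, pvals


# --- module set and annotation ---------------------------------------------

@dataclass
class ModuleSet:
    """Significantly reproducible training clusters with their centroids."""

    module_ids: list
    centroids: pd.DataFrame  # rows: module id, cols: retained measures
    training_sizes: dict
    igp_values: dict
    p_values: dict
    q_values: dict
    pi0: float
    q_threshold: float = 0.1
    seed: int | None = None
    parameters: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.module_ids)

    def to_json(self) -> str:
        payload = {
            "module_ids": [int(i) for i in self.module_ids],
            "centroids": {str(i): self.centroids.loc[i].tolist()
                          for i in self.module_ids},
            "measures": list(self.centroids.columns),
            "training_sizes": {str(k): int(v) for k, v in self.training_sizes.items()},
            "igp": {str(k): float(v) for k, v in self.igp_values.items()},
            "p": {str(k): float(v) for k, v in self.p_values.items()},
            "q": {str(k): float(v) for k, v in self.q_values.items()},
            "pi0": self.pi0,
            "q_threshold": self.q_threshold,
            "seed": self.seed,
            "parameters": self.parameters,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModuleSet":
        d = json.loads(text)
        ids = [int(i) for i in d["module_ids"]]
        centroids = pd.DataFrame(
            [d["centroids"][str(i)] for i in ids], index=ids,
            columns=d["measures"],
        )
        return cls(
            module_ids=ids, centroids=centroids,
            training_sizes={int(k): v for k, v in d["training_sizes"].items()},
            igp_values={int(k): v for k, v in d["igp"].items()},
            p_values={int(k): v for k, v in d["p"].items()},
            q_values={int(k): v for k, v in d["q"].items()},
            pi0=d["pi0"], q_threshold=d["q_threshold"], seed=d["seed"],
            parameters=d.get("parameters", {}),
        )


def assign_modules(data: pd.DataFrame, modules: ModuleSet) -> pd.DataFrame:
    """Annotate every excursion with its nearest significant module centroid.

    Returns a frame indexed like ``data`` with ``module`` (id) and
    ``distance`` columns; Euclidean ties break to the lower module id.
    """
    if len(modules) == 0:
        raise ValueError("empty module set")
    cols = list(modules.centroids.columns)
    X = data[cols].to_numpy(dtype=float)
    C = modules.centroids.to_numpy(dtype=float)
    d = cdist(X, C)
    nearest = d.argmin(axis=1)
    ids = np.asarray(modules.module_ids)
    return pd.DataFrame(
        {"module": ids[nearest], "distance": d[np.arange(len(X)), nearest]},
        index=data.index,
    )


def discover_modules(measures: pd.DataFrame, metadata: pd.DataFrame,
                     strata=("genotype", "sex", "phase"),
                     grid=None, deep_split: int = 4, min_cluster_size: int = 20,
                     fraction: float = 0.5, q_threshold: float = 0.1,
                     null_iterations: int = 200, nperm: int = 200,
                     seed: int | None = None) -> dict:
    """Run the full discovery pipeline on a scaled measure matrix.

    ``measures`` rows must align with ``metadata`` rows (same index).
    Returns a dict with the sweep, null-count test, ModuleSet, and the
    nearest-module annotation of every excursion.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_sweep, s_null, s_part, s_igp = ss.spawn(4)

    sweep = sweep_thresholds(measures, grid=grid, deep_split=deep_split,
                             min_cluster_size=min_cluster_size)
    selected = measures[sweep.selected_measures]

    observed, null_counts, null_p = null_cluster_count_test(
        selected, iterations=null_iterations,
        seed=s_null, deep_split=deep_split, min_cluster_size=min_cluster_size)

    train_idx, test_idx = partition_balanced(metadata, strata,
                                             fraction=fraction, seed=s_part)
    train, test = selected.loc[train_idx], selected.loc[test_idx]
    labels = cut_tree_hybrid(cluster_ward(train.to_numpy()),
                             deep_split=deep_split,
                             min_cluster_size=min_cluster_size)
    centroids = compute_centroids(labels, train)
    igp_obs, pvals = igp_permutation_test(
        test.to_numpy(), centroids.to_numpy(),
        nperm=nperm, seed=s_igp)
    q, pi0 = qvalues(pvals)
    cluster_ids = list(centroids.index)
    significant = [cid for cid, qv in zip(cluster_ids, q) if qv < q_threshold]
    modules = ModuleSet(
        module_ids=significant,
        centroids=centroids.loc[significant],
        training_sizes={cid: int((labels == cid).sum()) for cid in significant},
        igp_values={cid: float(v) for cid, v in zip(cluster_ids, igp_obs)
                    if cid in significant},
        p_values={cid: float(v) for cid, v in zip(cluster_ids, pvals)
                  if cid in significant},
        q_values={cid: float(v) for cid, v in zip(cluster_ids, q)
                  if cid in significant},
        pi0=pi0, q_threshold=q_threshold,
        seed=int(ss.entropy) if isinstance(ss.entropy, (int, np.integer))
        else None,
        parameters={"deep_split": deep_split,
                    "min_cluster_size": min_cluster_size,
                    "fraction": fraction,
                    "threshold": sweep.selected_threshold},
    )
    annotation = assign_modules(measures, modules) if significant else None
    return {
        "sweep": sweep,
        "null_test": {"observed": observed, "null_counts": null_counts,
                      "p": null_p},
        "train_index": train_idx,
        "test_index": test_idx,
        "training_labels": labels,
        "modules": modules,
        "assignments": annotation,
    }
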