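"""Clustering of enriched pathways by pairwise kappa statistics.

Enrichment typically returns many closely related pathways.  To reduce
them to representative groups, each pathway is encoded as a binary
membership vector over the significant input genes, and every pair is
compared with Cohen's kappa, a chance-corrected co-occurrence measure.
Two clustering modes are offered:

* **hierarchical** (default): agglomerative clustering with distance
  1 - kappa; the number of clusters is chosen automatically by
  maximizing the average silhouette width over all tree cuts.
* **fuzzy**: the DAVID-style heuristic in which each pathway with enough
  close neighbors (kappa at or above a threshold) seeds a group, groups
  sharing most of their members are merged, and a pathway may belong to
  several final groups.

Each cluster's representative is its pathway with the lowest adjusted p
value (ties: higher fold enrichment, then id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "KappaMatrix",
    "ClusterAssignment",
    "kappa_matrix",
    "hierarchical_cluster",
    "fuzzy_cluster",
]


@dataclass(frozen=True)
class KappaMatrix:
    """Symmetric pairwise kappa values between pathways."""

    pathway_ids: tuple[str, ...]
    values: np.ndarray  # shape (n, n), unit diagonal

    def __post_init__(self) -> None:
        n = len(self.pathway_ids)
        if self.values.shape != (n, n):
            raise ValueError("kappa matrix shape does not match pathway ids")

    def kappa(self, a: str, b: str) -> float:
        i, j = self.pathway_ids.index(a), self.pathway_ids.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster membership (one cluster per pathway for hierarchical, a
    set of clusters for fuzzy) plus per-cluster representatives."""

    membership: dict[str, frozenset[int]]
    representatives: dict[int, str]

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for pid, cids in self.membership.items():
            for cid in cids:
                out.setdefault(cid, set()).add(pid)
        return out

    def as_table(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.membership):
            for cid in sorted(self.membership[pid]):
                rows.append(
                    {
                        "ID": pid,
                        "cluster": cid,
                        "is_representative": self.representatives[cid] == pid,
                    }
                )
        return pd.DataFrame(rows, columns=["ID", "cluster", "is_representative"])


def _pairwise_kappa(u: np.ndarray, v: np.ndarray) -> float:
    n = len(u)
    a = int(np.sum(u & v))
    b = int(np.sum(u & ~v))
    c = int(np.sum(~u & v))
    d = n - a - b - c
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        # both vectors constant: identical -> perfect agreement, else none
        return 1.0 if np.array_equal(u, v) else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_matrix(result_table: pd.DataFrame, universe) -> KappaMatrix:
    """Pairwise kappa between pathways' input-gene membership vectors.

    ``universe`` is the set of significant input genes mapped to the PIN;
    a pathway's vector marks which universe genes it involves (the union
    of its up- and down-regulated columns).
    """
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("empty gene universe")
    ids = list(result_table["ID"])
    if len(ids) < 2:
        raise ValueError("nothing to cluster: need at least 2 pathways")
    vectors = {}
    for row in result_table.itertuples(index=False):
        genes = set(row.Up_regulated) | set(row.Down_regulated)
        vectors[row.ID] = np.array([g in genes for g in universe])
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pairwise_kappa(vectors[ids[i]], vectors[ids[j]])
    return KappaMatrix(pathway_ids=tuple(ids), values=mat)


def _representatives(
    clusters: dict[int, set[str]], result_table: pd.DataFrame
) -> dict[int, str]:
    info = {
        row.ID: (row.lowest_p, -row.Fold_Enrichment, row.ID)
        for row in result_table.itertuples(index=False)
    }
    return {cid: min(members, key=info.__getitem__) for cid, members in clusters.items()}


def hierarchical_cluster(
    kmat: KappaMatrix,
    result_table: pd.DataFrame,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering with distance 1 - kappa and automatic
    selection of the cluster count by average silhouette width.

    Every cut k in 2..n-1 of the dendrogram is evaluated; the cut with
    the highest average silhouette width wins (ties: smallest k).  With
    exactly two pathways the silhouette is undefined, so both go into a
    single cluster.
    """
    ids = list(kmat.pathway_ids)
    n = len(ids)
    dist = 1.0 - kmat.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)

    if n == 2:
        labels = np.array([1, 1])
    else:
        z = linkage(squareform(dist, checks=False), method=linkage_method)
        best_k, best_sil, best_labels = None, -np.inf, None
        for k in range(2, n):
            labels = fcluster(z, t=k, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            sil = silhouette_score(dist, labels, metric="precomputed")
            if sil > best_sil + 1e-12:
                best_k, best_sil, best_labels = k, sil, labels
        labels = best_labels if best_labels is not None else np.ones(n, dtype=int)

    clusters: dict[int, set[str]] = {}
    membership: dict[str, frozenset[int]] = {}
    for pid, label in zip(ids, labels):
        clusters.setdefault(int(label), set()).add(pid)
        membership[pid] = frozenset({int(label)})
    return ClusterAssignment(
        membership=membership,
        representatives=_representatives(clusters, result_table),
    )


def fuzzy_cluster(
    kmat: KappaMatrix,
    result_table: pd.DataFrame,
    kappa_threshold: float = 0.35,
    min_neighbors: int = 3,
    merge_overlap: float = 0.5,
) -> ClusterAssignment:
    """DAVID-style fuzzy clustering; a pathway may join several clusters.

    1. Every pathway whose close-neighbor set (others with kappa >=
       ``kappa_threshold``) has at least ``min_neighbors`` members seeds
       an initial group of itself plus those neighbors.
    2. Any two groups sharing more than ``merge_overlap`` of the smaller
       group's members are merged, repeatedly, until stable.
    3. A pathway belongs to every surviving group that contains it;
       pathways in no group become singletons.
    """
    ids = list(kmat.pathway_ids)
    n = len(ids)
    groups: list[set[str]] = []
    for i in range(n):
        neighbors = {ids[j] for j in range(n) if j != i and kmat.values[i, j] >= kappa_threshold}
        if len(neighbors) >= min_neighbors:
            groups.append({ids[i]} | neighbors)

    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                shared = len(groups[i] & groups[j])
                smaller = min(len(groups[i]), len(groups[j]))
                if smaller and shared / smaller > merge_overlap:
                    groups[i] |= groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break

    covered = set().union(*groups) if groups else set()
    for pid in ids:
        if pid not in covered:
            groups.append({pid})

    clusters = {cid: members for cid, members in enumerate(groups, start=1)}
    membership: dict[str, frozenset[int]] = {
        pid: frozenset(cid for cid, members in clusters.items() if pid in members)
        for pid in ids
    }
    return ClusterAssignment(
        membership=membership,
        representatives=_representatives(clusters, result_table),
    )
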