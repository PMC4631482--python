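"""Dataset selection by hierarchical cluster analysis of pairwise CC.

Partial datasets from different crystals are compared by the Pearson
correlation CC_I(i,j) of their intensities over the unique reflections
they have in common.  The correlations are turned into distances
``dist = sqrt(1 - CC²)``, clustered agglomeratively (average linkage by
default) and the dendrogram is cut at a height — 0.15 by convention —
below which datasets are considered isomorphous enough to merge.  The
largest cluster under the cut is the merge candidate.

Merohedral indexing ambiguities are resolved before correlation: each
dataset is remapped through whichever ambiguity operator (including the
identity) best correlates it with the first dataset, which serves as
the indexing reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .reflections import ReflectionSet, SymmetrySetting, reduce_array_to_asu

__all__ = [
    "CCMatrix",
    "Dendrogram",
    "ClusterSelection",
    "pairwise_cc",
    "cc_to_distance",
    "hca",
    "cut",
    "resolve_indexing",
]


@dataclass
class CCMatrix:
    """Symmetric matrix of pairwise dataset correlations.

    ``missing`` marks pairs with fewer common uniques than the cutoff;
    their CC is NaN.
    """

    cc: np.ndarray
    n_common: np.ndarray
    missing: np.ndarray
    labels: list[str]


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage form.

    ``merges`` rows are (node_a, node_b, height, size); leaves are
    0..n-1, internal node i is n+i.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        n = self.n_leaves
        nodes: dict[int, str] = {i: str(self.labels[i]) for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + i] = h
        return nodes[n + len(self.merges) - 1] + ";"


@dataclass
class ClusterSelection:
    cutoff: float
    membership: np.ndarray          # cluster id per leaf
    main_cluster: list[int]         # leaf indices of the selected cluster
    labels: list[str] = field(default_factory=list)

    def main_labels(self) -> list[str]:
        return [self.labels[i] for i in self.main_cluster] if self.labels else []


def pairwise_cc(sets: list[ReflectionSet], min_common: int = 30) -> CCMatrix:
    """CC_I(i,j) over the ASU-common unique intensities of each pair.

    Each set's own duplicate observations are merged (inverse-variance
    weighted mean) before comparison.  Pairs sharing fewer than
    ``min_common`` uniques are marked missing.
    """
    n = len(sets)
    merged = [s.merged_by_unique() for s in sets]
    cc = np.full((n, n), np.nan)
    n_common = np.zeros((n, n), dtype=int)
    np.fill_diagonal(cc, 1.0)
    for i in range(n):
        n_common[i, i] = len(merged[i])
        for j in range(i + 1, n):
            common = merged[i].keys() & merged[j].keys()
            n_common[i, j] = n_common[j, i] = len(common)
            if len(common) < min_common:
                continue
            xi = np.array([merged[i][k][0] for k in common])
            xj = np.array([merged[j][k][0] for k in common])
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            cc[i, j] = cc[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    missing = ~np.isfinite(cc)
    return CCMatrix(cc=cc, n_common=n_common, missing=missing,
                    labels=[s.label or str(i) for i, s in enumerate(sets)])


def cc_to_distance(cc) -> np.ndarray:
    """dist = sqrt(1 - CC²); undefined (NaN) correlations map to 1."""
    cc = np.asarray(cc, dtype=float)
    with np.errstate(invalid="ignore"):
        dist = np.sqrt(np.clip(1.0 - cc**2, 0.0, None))
    dist = np.where(np.isfinite(cc), dist, 1.0)
    return dist if dist.ndim else float(dist)


def hca(dist: np.ndarray, method: str = "average", labels=None) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two datasets to cluster")
    d = dist.copy()
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry for squareform
    merges = linkage(squareform(d, checks=False), method=method)
    return Dendrogram(merges=merges, labels=list(labels) if labels is not None
                      else [str(i) for i in range(n)])


def cut(dend: Dendrogram, height: float, dist: np.ndarray | None = None) -> ClusterSelection:
    """Clusters = connected components of merges strictly below ``height``.

    The main cluster is the largest; size ties go to the cluster with the
    lower mean intra-cluster distance (needs ``dist``; otherwise first in
    leaf order).
    """
    n = dend.n_leaves
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    node_root = {i: i for i in range(n)}
    for i, (a, b, h, _) in enumerate(dend.merges):
        ra, rb = find(node_root[int(a)]), find(node_root[int(b)])
        if h < height:
            parent[rb] = ra
        node_root[n + i] = ra if h < height else find(node_root[int(a)])
    clusters: dict[int, list[int]] = {}
    for leaf in range(n):
        clusters.setdefault(find(leaf), []).append(leaf)
    membership = np.empty(n, dtype=int)
    for cid, (root, leaves) in enumerate(sorted(clusters.items())):
        for leaf in leaves:
            membership[leaf] = cid
    groups = sorted(clusters.values(), key=len, reverse=True)
    best_size = len(groups[0])
    tied = [g for g in groups if len(g) == best_size]
    if len(tied) > 1 and dist is not None and best_size > 1:
        def mean_intra(g):
            sub = dist[np.ix_(g, g)]
            return sub[np.triu_indices(len(g), 1)].mean()
        main = min(tied, key=mean_intra)
    else:
        main = tied[0]
    return ClusterSelection(cutoff=height, membership=membership,
                            main_cluster=sorted(main), labels=dend.labels)


def resolve_indexing(
    sets: list[ReflectionSet],
    setting: SymmetrySetting | None = None,
    min_common: int = 30,
) -> tuple[list[ReflectionSet], list[dict]]:
    """Resolve merohedral indexing ambiguities against the first dataset.

    Each set is remapped through the ambiguity operator (identity
    included) that maximises its CC with the reference over common
    uniques.  Sets that never reach ``min_common`` commons are left
    unchanged and flagged.  Returns the reindexed sets and a per-set
    report (chosen operator index, CC, flag).
    """
    if not sets:
        return [], []
    setting = setting or sets[0].setting
    ops = [np.eye(3, dtype=int)] + [np.asarray(m, dtype=int) for m in setting.ambiguity_ops]
    if len(ops) == 1:
        return list(sets), [{"op_index": 0, "cc": None, "flagged": False} for _ in sets]
    ref = sets[0].merged_by_unique()
    out: list[ReflectionSet] = []
    report: list[dict] = []
    for i, s in enumerate(sets):
        best = None
        for oi, op in enumerate(ops):
            hkl = reduce_array_to_asu(s.hkl @ op.T, setting)
            cand = ReflectionSet(hkl=hkl, intensity=s.intensity, sigma=s.sigma,
                                 setting=setting, label=s.label, true_class=s.true_class,
                                 meta=dict(s.meta))
            merged = cand.merged_by_unique()
            common = ref.keys() & merged.keys()
            if len(common) < min_common:
                continue
            xi = np.array([ref[k][0] for k in common])
            xj = np.array([merged[k][0] for k in common])
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            cc = float(np.corrcoef(xi, xj)[0, 1])
            if best is None or cc > best[0]:
                best = (cc, oi, cand)
        if best is None:
            out.append(s)
            report.append({"op_index": 0, "cc": None, "flagged": True})
        else:
            cc, oi, cand = best
            out.append(cand)
            report.append({"op_index": oi, "cc": cc, "flagged": False})
    return out, report
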