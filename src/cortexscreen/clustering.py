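"""Chemical class discovery from expression profiles.

Average-linkage (UPGMA) hierarchical clustering with 1 - Pearson
correlation distance, followed by the membership rule: candidate clusters
are the maximal dendrogram subtrees whose leaves number at least three and
whose pairwise Spearman correlations (over all retained genes) all strictly
exceed 0.2. Candidates whose mean silhouette width (same 1 - Pearson
distance, computed over clustered chemicals only) is not positive are then
removed, their members becoming unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata
from sklearn.metrics import silhouette_samples

from .preprocess import ChemicalProfileMatrix

__all__ = [
    "Dendrogram",
    "ClusterResult",
    "build_dendrogram",
    "assign_cluster_membership",
    "silhouette_filter",
    "discover_clusters",
    "pearson_distance_matrix",
    "spearman_matrix",
]

logger = logging.getLogger(__name__)

MIN_CLUSTER_SIZE = 3
MIN_PAIRWISE_SPEARMAN = 0.2


def _profile_frame(profiles: ChemicalProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(profiles, ChemicalProfileMatrix):
        return profiles.values
    return profiles


def pearson_distance_matrix(profiles: ChemicalProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between chemical profile columns."""
    vals = _profile_frame(profiles)
    x = vals.to_numpy(dtype=float)
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"constant profile(s), correlation undefined: {list(vals.columns[flat])}"
        )
    corr = np.corrcoef(x.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=vals.columns, columns=vals.columns)


def spearman_matrix(profiles: ChemicalProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between chemical profile columns."""
    vals = _profile_frame(profiles)
    ranks = np.apply_along_axis(rankdata, 0, vals.to_numpy(dtype=float))
    corr = np.corrcoef(ranks.T)
    return pd.DataFrame(corr, index=vals.columns, columns=vals.columns)


@dataclass
class Dendrogram:
    """UPGMA merge tree over chemicals with its distance matrix."""

    linkage: np.ndarray
    labels: list[str]
    distances: pd.DataFrame

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def subtree_leafsets(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes, indexed by merge order."""
        n = len(self.labels)
        sets: list[frozenset[str]] = [frozenset([lb]) for lb in self.labels]
        for a, b, *_ in self.linkage:
            sets.append(sets[int(a)] | sets[int(b)])
        return sets[n:]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


@dataclass
class ClusterResult:
    """Candidate and final clusters with the statistics behind each rule."""

    candidate_clusters: list[list[str]]
    final_clusters: list[list[str]]
    membership: dict[str, int | None]
    min_pairwise_spearman: list[float]   # per final cluster
    mean_silhouette: list[float]         # per candidate cluster (nan = undefined)
    removed_clusters: list[list[str]]


def build_dendrogram(profiles: ChemicalProfileMatrix | pd.DataFrame) -> Dendrogram:
    """Average-linkage tree on 1 - Pearson distances between profiles.

    scipy's UPGMA breaks distance ties by cluster index, which is label
    order here since columns enter in their given order.
    """
    vals = _profile_frame(profiles)
    if vals.shape[1] < 2:
        raise ValueError("need at least two chemicals to cluster")
    if vals.shape[0] < 2:
        raise ValueError("need at least two genes to cluster")
    d = pearson_distance_matrix(vals)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    condensed = d.to_numpy()[iu]
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=z, labels=list(vals.columns), distances=d)


def assign_cluster_membership(
    dendrogram: Dendrogram,
    profiles: ChemicalProfileMatrix | pd.DataFrame,
    min_size: int = MIN_CLUSTER_SIZE,
    min_spearman: float = MIN_PAIRWISE_SPEARMAN,
    exclude: tuple[str, ...] = (),
) -> list[list[str]]:
    """Candidate clusters: maximal dendrogram subtrees whose leaf sets have
    at least ``min_size`` members and all pairwise Spearman correlations
    strictly above ``min_spearman``.

    Maximality is resolved top-down, so candidates are disjoint. Labels in
    ``exclude`` (the vehicle) never join a candidate.
    """
    vals = _profile_frame(profiles)
    rho = spearman_matrix(vals)
    labels = dendrogram.labels
    pos = {lb: i for i, lb in enumerate(labels)}
    rho_np = rho.loc[labels, labels].to_numpy()
    n = len(labels)

    tree = hierarchy.to_tree(dendrogram.linkage)

    def leafset(node) -> list[int]:
        return node.pre_order(lambda x: x.id)

    def qualifies(ids: list[int]) -> bool:
        if len(ids) < min_size:
            return False
        if any(labels[i] in exclude for i in ids):
            return False
        sub = rho_np[np.ix_(ids, ids)]
        off = sub[~np.eye(len(ids), dtype=bool)]
        return bool((off > min_spearman).all())

    candidates: list[list[str]] = []

    def descend(node) -> None:
        if node.is_leaf():
            return
        ids = leafset(node)
        if qualifies(ids):
            candidates.append(sorted(labels[i] for i in ids))
            return
        descend(node.left)
        descend(node.right)

    descend(tree)
    candidates.sort(key=lambda c: (-len(c), c))
    del pos, n
    return candidates


def silhouette_filter(
    candidates: list[list[str]],
    profiles: ChemicalProfileMatrix | pd.DataFrame,
) -> ClusterResult:
    """Retain candidates with strictly positive mean silhouette width.

    Silhouettes use the clustering distance (1 - Pearson) and are computed
    over clustered chemicals only. With a single candidate the silhouette
    is undefined; the candidate is retained and flagged with NaN. Members
    of removed candidates become unassigned.
    """
    vals = _profile_frame(profiles)
    if not candidates:
        return ClusterResult([], [], {c: None for c in vals.columns}, [], [], [])

    clustered = [c for cl in candidates for c in cl]
    cluster_of = {c: k for k, cl in enumerate(candidates) for c in cl}
    if len(clustered) != len(set(clustered)):
        raise ValueError("candidate clusters are not disjoint")

    if len(candidates) == 1:
        mean_sil = [float("nan")]
        finals = [candidates[0]]
        removed: list[list[str]] = []
    else:
        d = pearson_distance_matrix(vals[clustered])
        lab = np.array([cluster_of[c] for c in clustered])
        sil = silhouette_samples(d.to_numpy(), lab, metric="precomputed")
        mean_sil = [float(sil[lab == k].mean()) for k in range(len(candidates))]
        finals = [cl for cl, s in zip(candidates, mean_sil) if s > 0]
        removed = [cl for cl, s in zip(candidates, mean_sil) if not s > 0]

    rho = spearman_matrix(vals)
    min_rho = []
    for cl in finals:
        sub = rho.loc[cl, cl].to_numpy()
        off = sub[~np.eye(len(cl), dtype=bool)]
        min_rho.append(float(off.min()))

    membership: dict[str, int | None] = {c: None for c in vals.columns}
    for k, cl in enumerate(finals):
        for c in cl:
            membership[c] = k

    return ClusterResult(
        candidate_clusters=candidates,
        final_clusters=finals,
        membership=membership,
        min_pairwise_spearman=min_rho,
        mean_silhouette=mean_sil,
        removed_clusters=removed,
    )


def discover_clusters(
    profiles: ChemicalProfileMatrix | pd.DataFrame,
    min_size: int = MIN_CLUSTER_SIZE,
    min_spearman: float = MIN_PAIRWISE_SPEARMAN,
    exclude_vehicle: bool = True,
) -> ClusterResult:
    """Full discovery: build tree, apply membership rule, filter by
    silhouette. Asserts the three printed rules on every final cluster."""
    vals = _profile_frame(profiles)
    exclude: tuple[str, ...] = ()
    if exclude_vehicle and isinstance(profiles, ChemicalProfileMatrix) and profiles.vehicle:
        exclude = (profiles.vehicle,)
    dend = build_dendrogram(vals)
    candidates = assign_cluster_membership(
        dend, vals, min_size=min_size, min_spearman=min_spearman, exclude=exclude
    )
    result = silhouette_filter(candidates, vals)
    logger.info(
        "cluster discovery: %d candidates, %d final clusters",
        len(result.candidate_clusters), len(result.final_clusters),
    )
    for cl, rho_min in zip(result.final_clusters, result.min_pairwise_spearman):
        assert len(cl) >= min_size
        assert rho_min > min_spearman
    for cl in result.final_clusters:
        k = result.membership[cl[0]]
        if len(result.candidate_clusters) > 1:
            idx = result.candidate_clusters.index(cl)
            assert result.mean_silhouette[idx] > 0
        del k
    return result
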