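"""Clustering of chemicals from in vitro assay AC50 profiles.

Assays are filtered for completeness (>= 99% of chemicals with data) and
for activity (>= 5 chemicals with AC50 <= 10 uM), AC50 values are turned
into a potency score, and chemicals are hierarchically clustered with the
same average-linkage / Pearson-distance recipe used for expression
profiles. The resulting grouping can be compared with expression-derived
clusters via the adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from .clustering import ClusterResult

__all__ = [
    "AssayClusterResult",
    "filter_assays",
    "potency_score",
    "transform_and_cluster",
    "compare_groupings",
]

ACTIVE_CUTOFF_UM = 10.0
MIN_ACTIVE_CHEMICALS = 5
MIN_COMPLETENESS = 0.99


@dataclass
class AssayClusterResult:
    """Chemical grouping from assay potency profiles."""

    grouping: dict[str, int]
    linkage: np.ndarray
    labels: list[str]
    scores: pd.DataFrame
    ari_vs_expression: float | None = None


def filter_assays(
    matrix: pd.DataFrame,
    completeness: float = MIN_COMPLETENESS,
    min_active: int = MIN_ACTIVE_CHEMICALS,
    active_cutoff_um: float = ACTIVE_CUTOFF_UM,
) -> pd.DataFrame:
    """Keep assays (columns) with data for at least ``completeness`` of the
    chemicals and at least ``min_active`` active chemicals
    (AC50 <= ``active_cutoff_um``; the boundary counts as active)."""
    if matrix.empty:
        raise ValueError("assay matrix is empty")
    present = matrix.notna().mean(axis=0)
    n_active = (matrix <= active_cutoff_um).sum(axis=0)
    keep = (present >= completeness) & (n_active >= min_active)
    if not keep.any():
        raise ValueError("no assays survive the completeness/activity filters")
    return matrix.loc[:, keep]


def potency_score(
    ac50_um: pd.DataFrame,
    active_cutoff_um: float = ACTIVE_CUTOFF_UM,
) -> pd.DataFrame:
    """Default potency transform: log10(cutoff / AC50) for active pairs
    (monotone decreasing in AC50, zero at the activity cutoff), zero for
    inactive or missing pairs."""
    x = ac50_um.to_numpy(dtype=float)
    score = np.where(
        np.isfinite(x) & (x <= active_cutoff_um) & (x > 0),
        np.log10(active_cutoff_um / np.where(x > 0, x, 1.0)),
        0.0,
    )
    return pd.DataFrame(score, index=ac50_um.index, columns=ac50_um.columns)


def transform_and_cluster(
    matrix: pd.DataFrame,
    n_groups: int | None = None,
    expression_clusters: ClusterResult | dict[str, int | None] | None = None,
    transform: Callable[[pd.DataFrame], pd.DataFrame] = potency_score,
) -> AssayClusterResult:
    """Cluster chemicals on transformed AC50 profiles and optionally score
    agreement with expression-derived clusters.

    Constant score columns are dropped with a warning; chemicals with no
    activity at all (constant all-zero profiles, undefined correlation)
    are dropped with a warning as well. The tree is cut into ``n_groups``
    flat groups (default: the number of expression clusters, else the
    square root of the chemical count).
    """
    scores = transform(matrix)
    const_cols = scores.columns[scores.nunique(axis=0) <= 1]
    if len(const_cols):
        warnings.warn(f"dropping constant assay column(s): {list(const_cols)}")
        scores = scores.drop(columns=const_cols)
    const_rows = scores.index[scores.nunique(axis=1) <= 1]
    if len(const_rows):
        warnings.warn(
            f"dropping chemical(s) with constant potency profile: {list(const_rows)}"
        )
        scores = scores.drop(index=const_rows)
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("not enough chemicals/assays left to cluster")

    x = scores.to_numpy(dtype=float)
    corr = np.corrcoef(x)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    iu = np.triu_indices(len(scores), k=1)
    z = hierarchy.linkage(d[iu], method="average")

    expr_membership: dict[str, int | None] | None = None
    if isinstance(expression_clusters, ClusterResult):
        expr_membership = expression_clusters.membership
    elif expression_clusters is not None:
        expr_membership = dict(expression_clusters)

    if n_groups is None:
        if expr_membership is not None:
            n_groups = max(
                len({v for v in expr_membership.values() if v is not None}), 2
            )
        else:
            n_groups = max(int(np.sqrt(len(scores))), 2)
    flat = hierarchy.fcluster(z, t=n_groups, criterion="maxclust")
    grouping = {c: int(g) for c, g in zip(scores.index, flat)}

    ari = None
    if expr_membership is not None:
        ari = compare_groupings(grouping, expr_membership)

    return AssayClusterResult(
        grouping=grouping,
        linkage=z,
        labels=list(scores.index),
        scores=scores,
        ari_vs_expression=ari,
    )


def compare_groupings(
    grouping: dict[str, int],
    expression_membership: dict[str, int | None],
) -> float:
    """Adjusted Rand index between an assay grouping and expression cluster
    membership over the chemicals present in both (unassigned chemicals map
    to their own background label)."""
    common = sorted(set(grouping) & set(expression_membership))
    if len(common) < 2:
        raise ValueError("fewer than two chemicals in common")
    a = [grouping[c] for c in common]
    b = [
        expression_membership[c] if expression_membership[c] is not None else -1
        for c in common
    ]
    return float(adjusted_rand_score(a, b))
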