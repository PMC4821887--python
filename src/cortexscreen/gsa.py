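"""Gene set analysis of discovered clusters against all other chemicals.

Implements the maxmean gene-set statistic of Efron & Tibshirani with
restandardization against the all-gene catalog, a permutation null built by
shuffling chemical cluster labels, and a per-direction plug-in permutation
FDR. Each cluster is tested separately against all other chemicals; the
enrichment score is signed so that negative values mean lower relative
expression in the cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "GeneSet",
    "GsaResult",
    "PathwaySummaryMatrix",
    "filter_gene_sets",
    "gene_level_statistic",
    "maxmean_score",
    "gsa_test",
    "summarize_pathways",
]

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 10
MAX_SET_SIZE = 1500
DEFAULT_N_PERM = 500
DEFAULT_FDR = 0.1


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; ``direction`` optionally tags up/down collections."""

    name: str
    genes: tuple[str, ...]
    direction: str | None = None
    note: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GsaResult:
    """Per (gene set, cluster) signed enrichment score and permutation FDR."""

    table: pd.DataFrame   # columns: gene_set, cluster, enrichment_score, fdr, n_perm
    n_perm: int
    fdr_threshold: float
    seed: int | None = None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.fdr_threshold]


@dataclass
class PathwaySummaryMatrix:
    """Pathways x chemicals median-summary matrix, row-centred, with the
    pathway dendrogram order and the per-(pathway, cluster) significance
    mask carried through."""

    values: pd.DataFrame
    significance: pd.DataFrame   # pathways x clusters, boolean
    pathway_order: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def filter_gene_sets(
    collection: list[GeneSet],
    retained_genes: list[str] | pd.Index,
    kme_scores: dict[str, dict[str, float]] | None = None,
    kme_threshold: float = 0.4,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> list[GeneSet]:
    """Intersect each set with the retained genes and keep sets whose
    surviving size lies in [min_size, max_size].

    ``kme_scores`` optionally maps set name -> gene -> module-membership
    score; genes scoring below ``kme_threshold`` are dropped from that set
    *before* the size filter (the oversized-module trimming rule).
    """
    retained = set(retained_genes)
    out: list[GeneSet] = []
    names = set()
    for gs in collection:
        if gs.name in names:
            raise ValueError(f"duplicate gene set name: {gs.name}")
        names.add(gs.name)
        genes = list(gs.genes)
        if kme_scores and gs.name in kme_scores:
            scores = kme_scores[gs.name]
            genes = [g for g in genes if scores.get(g, 0.0) >= kme_threshold]
        genes = [g for g in genes if g in retained]
        if min_size <= len(genes) <= max_size:
            out.append(GeneSet(gs.name, tuple(genes), gs.direction, gs.note))
    if not out:
        raise ValueError("no gene sets survive filtering")
    return out


def gene_level_statistic(
    profiles: pd.DataFrame,
    cluster_members: list[str],
    s0: float | None = None,
) -> np.ndarray:
    """Moderated two-sample statistic per gene: cluster chemicals versus all
    other chemicals, pooled variance, with an additive variance floor
    ``s0`` in the denominator (default: the median pooled standard error
    over genes, SAM-style)."""
    members = [c for c in cluster_members if c in profiles.columns]
    others = [c for c in profiles.columns if c not in set(members)]
    if len(members) < 2 or len(others) < 2:
        raise ValueError("need >= 2 members and >= 2 non-members")
    x1 = profiles[members].to_numpy(dtype=float)
    x2 = profiles[others].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = float(np.median(se))
        if s0 == 0.0:
            s0 = 1e-8
            logger.warning("all pooled variances are zero; using absolute floor")
    return (m1 - m2) / (se + s0)


def maxmean_score(
    z: np.ndarray,
    set_index: np.ndarray,
    restandardize: bool = True,
) -> float:
    """Maxmean statistic of a gene set given all-gene statistics ``z``.

    s+ is the set mean of the positive parts, s- of the negative parts;
    the raw score is whichever one-sided mean is larger, signed. With
    restandardization each one-sided mean is centred and scaled by the
    all-gene catalog of positive/negative parts (sd of a random set mean
    of the same size) before the sign decision.
    """
    zs = z[set_index]
    m = len(zs)
    if m == 0:
        raise ValueError("empty gene set")
    s_pos = np.maximum(zs, 0.0).mean()
    s_neg = np.maximum(-zs, 0.0).mean()
    if not restandardize:
        return float(s_pos if s_pos >= s_neg else -s_neg)
    pos_all = np.maximum(z, 0.0)
    neg_all = np.maximum(-z, 0.0)
    sd_pos = pos_all.std(ddof=1) / np.sqrt(m)
    sd_neg = neg_all.std(ddof=1) / np.sqrt(m)
    sd_pos = sd_pos if sd_pos > 0 else 1e-12
    sd_neg = sd_neg if sd_neg > 0 else 1e-12
    r_pos = (s_pos - pos_all.mean()) / sd_pos
    r_neg = (s_neg - neg_all.mean()) / sd_neg
    return float(r_pos if r_pos >= r_neg else -r_neg)


def _scores_for_labels(
    x: np.ndarray,
    member_mask: np.ndarray,
    set_indices: list[np.ndarray],
    s0: float | None,
) -> np.ndarray:
    """Maxmean scores of all sets for one cluster-vs-rest split."""
    n1 = int(member_mask.sum())
    n2 = member_mask.size - n1
    x1 = x[:, member_mask]
    x2 = x[:, ~member_mask]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    floor = float(np.median(se)) if s0 is None else s0
    if floor == 0.0:
        floor = 1e-8
    z = (m1 - m2) / (se + floor)
    return np.array([maxmean_score(z, idx) for idx in set_indices])


def _plugin_fdr(observed: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Per-direction plug-in permutation FDR.

    For a positively scored set, FDR = (mean permutation count of positive
    scores >= s) / (observed count of positive scores >= s), clipped to
    [0, 1]; negatively scored sets are handled symmetrically. FDR is then
    made monotone non-increasing in |score|.
    """
    n_sets = observed.size
    fdr = np.ones(n_sets)
    for sign in (1, -1):
        mask = (observed * sign) > 0
        if not mask.any():
            continue
        svals = observed[mask] * sign
        pvals = (perm * sign).ravel()
        pvals = pvals[pvals > 0]
        n_perm = perm.shape[0]
        order = np.argsort(svals)
        sorted_s = svals[order]
        perm_ge = pvals.size - np.searchsorted(np.sort(pvals), sorted_s, side="left")
        obs_ge = svals.size - np.searchsorted(sorted_s, sorted_s, side="left")
        est = (perm_ge / n_perm) / np.maximum(obs_ge, 1)
        est = np.clip(est, 0.0, 1.0)
        # monotone non-increasing in |score|: a set more extreme than one
        # already called at FDR q can always be called at q as well
        est = np.minimum.accumulate(est)
        out = np.empty_like(est)
        out[order] = est  # est is aligned with sorted_s; invert the sort
        fdr[mask] = out
    return fdr


def gsa_test(
    profiles: pd.DataFrame,
    clusters: list[list[str]],
    collection: list[GeneSet],
    n_perm: int = DEFAULT_N_PERM,
    fdr_threshold: float = DEFAULT_FDR,
    seed: int | None = None,
    s0: float | None = None,
    exclude: tuple[str, ...] = (),
) -> GsaResult:
    """Score every (gene set, cluster) pair with a permutation FDR.

    The null is built by permuting the cluster-membership labels over
    chemicals ``n_perm`` times; FDR is estimated per direction from the
    pooled permutation scores within each cluster.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not clusters:
        raise ValueError("need at least one cluster to test")
    cols = [c for c in profiles.columns if c not in exclude]
    x = profiles[cols].to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(profiles.index)}
    set_indices = [
        np.array([gene_pos[g] for g in gs.genes if g in gene_pos], dtype=np.int64)
        for gs in collection
    ]
    bad = [gs.name for gs, idx in zip(collection, set_indices) if idx.size == 0]
    if bad:
        raise ValueError(f"gene set(s) with no genes in the profile matrix: {bad}")

    rng = np.random.default_rng(seed)
    rows = []
    for k, members in enumerate(clusters):
        mask = np.array([c in set(members) for c in cols])
        n1 = int(mask.sum())
        if n1 < 2 or mask.size - n1 < 2:
            warnings.warn(f"cluster {k} too small to test; skipped")
            continue
        from math import comb
        if comb(mask.size, n1) < 10 * n_perm:
            warnings.warn(
                f"cluster {k}: only {comb(mask.size, n1)} distinct label splits "
                f"for {n_perm} permutations"
            )
        observed = _scores_for_labels(x, mask, set_indices, s0)
        perm_scores = np.empty((n_perm, len(collection)))
        for b in range(n_perm):
            pm = np.zeros(mask.size, dtype=bool)
            pm[rng.choice(mask.size, size=n1, replace=False)] = True
            perm_scores[b] = _scores_for_labels(x, pm, set_indices, s0)
        fdr = _plugin_fdr(observed, perm_scores)
        for gs, s, q in zip(collection, observed, fdr):
            rows.append((gs.name, k, float(s), float(q), n_perm))

    table = pd.DataFrame(
        rows, columns=["gene_set", "cluster", "enrichment_score", "fdr", "n_perm"]
    )
    return GsaResult(table=table, n_perm=n_perm, fdr_threshold=fdr_threshold, seed=seed)


def summarize_pathways(
    profiles: pd.DataFrame,
    significant_sets: list[GeneSet],
    result: GsaResult | None = None,
) -> PathwaySummaryMatrix:
    """Median-summarize each significant pathway per chemical, median-centre
    the rows, and hierarchically cluster the pathways (average linkage,
    Pearson distance) while keeping the chemical order unchanged."""
    if not significant_sets:
        raise ValueError("need at least one significant gene set")
    gene_pos = profiles.index
    rows = {}
    for gs in significant_sets:
        genes = [g for g in gs.genes if g in gene_pos]
        if not genes:
            raise ValueError(f"gene set {gs.name} has no genes in the profiles")
        rows[gs.name] = profiles.loc[genes].median(axis=0)
    mat = pd.DataFrame(rows).T
    mat.columns = profiles.columns
    mat = mat.sub(mat.median(axis=1), axis=0)

    order = list(mat.index)
    if len(mat) > 2:
        x = mat.to_numpy(dtype=float)
        sd = x.std(axis=1)
        safe = x.copy()
        # constant rows get zero correlation distance contribution
        safe[sd == 0] += np.linspace(0, 1e-9, x.shape[1])
        corr = np.corrcoef(safe)
        d = 1.0 - corr
        iu = np.triu_indices(len(mat), k=1)
        z = hierarchy.linkage(d[iu], method="average")
        order = [mat.index[i] for i in hierarchy.leaves_list(z)]

    sig = pd.DataFrame()
    if result is not None and len(result.table):
        sig = (
            result.table.assign(is_sig=result.table["fdr"] < result.fdr_threshold)
            .pivot(index="gene_set", columns="cluster", values="is_sig")
            .reindex(mat.index)
            .fillna(False)
        )
    return PathwaySummaryMatrix(values=mat, significance=sig, pathway_order=order)
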