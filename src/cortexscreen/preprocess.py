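"""Expression preprocessing: counts to per-chemical profiles.

The pipeline runs in a fixed printed order, enforced through stage tags:

    RPKM -> expressed/length filter -> log10 -> quantile normalization ->
    median-centre -> batch removal -> median-centre -> s.d. filter ->
    replicate median

Calling an operation out of order raises :class:`PipelineOrderError`.
All thresholds use strict inequalities: a gene must be non-zero in more
than 90% of samples, longer than 500 bp, and have s.d. exceeding 0.1
(n-1 denominator) to survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PipelineOrderError",
    "ExpressionMatrix",
    "ChemicalProfileMatrix",
    "compute_rpkm",
    "filter_expressed_genes",
    "log_quantile_normalize",
    "median_center_genes",
    "remove_batch_effects",
    "variability_filter",
    "combine_replicates",
    "preprocess_pipeline",
    "batch_variance_fraction",
]

#: default offset added before log10, since up to 10% of samples may still
#: have zero RPKM after the expression filter
LOG_OFFSET = 0.01

STAGE_ORDER = [
    "counts",
    "rpkm",
    "expressed_filter",
    "log_qnorm",
    "median_center",
    "batch_corrected",
    "median_center_2",
    "sd_filter",
]


class PipelineOrderError(RuntimeError):
    """An operation was applied out of the prescribed pipeline order."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with its pipeline provenance.

    ``stage`` is the tag of the last applied operation; ``provenance``
    accumulates all applied stages in order.
    """

    values: pd.DataFrame
    stage: str
    annotation: pd.DataFrame | None = None
    design: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.provenance:
            self.provenance = [self.stage]

    def _advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        return dc_replace(
            self, values=values, stage=stage, provenance=self.provenance + [stage]
        )

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise PipelineOrderError(
                f"operation requires stage in {allowed}, matrix is at '{self.stage}'"
            )


@dataclass
class ChemicalProfileMatrix:
    """Genes x chemicals profiles: the clustering substrate.

    One column per chemical (replicates collapsed by the median); genes are
    exactly those surviving the expression/length and variability filters.
    """

    values: pd.DataFrame
    provenance: list[str]
    retained_gene_ids: list[str]
    vehicle: str | None = None


def as_expression_matrix(
    counts: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    stage: str = "counts",
) -> ExpressionMatrix:
    return ExpressionMatrix(values=counts, stage=stage, annotation=annotation, design=design)


# ---------------------------------------------------------------------------

def compute_rpkm(counts: ExpressionMatrix | pd.DataFrame,
                 annotation: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total_reads[s]),
    with the per-sample total taken as the column sum.
    """
    if isinstance(counts, pd.DataFrame):
        counts = as_expression_matrix(counts, annotation=annotation)
    counts.require_stage("counts")
    ann = annotation if annotation is not None else counts.annotation
    if ann is None:
        raise ValueError("gene annotation with length_bp is required")
    vals = counts.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = ann.loc[vals.index, "length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = vals.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample(s) with zero total reads: {list(vals.columns[zero])}")
    rpkm = vals.to_numpy(dtype=float) * 1.0e9 / (lengths[:, None] * totals[None, :])
    out = pd.DataFrame(rpkm, index=vals.index, columns=vals.columns)
    return dc_replace(counts, values=out, stage="rpkm",
                      provenance=counts.provenance + ["rpkm"], annotation=ann)


def filter_expressed_genes(matrix: ExpressionMatrix,
                           min_nonzero_frac: float = 0.9,
                           min_length_bp: int = 500) -> ExpressionMatrix:
    """Keep genes with RPKM > 0 in strictly more than 90% of samples and
    length strictly greater than 500 bp."""
    matrix.require_stage("rpkm")
    if matrix.annotation is None:
        raise ValueError("annotation required for the length filter")
    vals = matrix.values
    nonzero_frac = (vals.to_numpy() > 0).mean(axis=1)
    lengths = matrix.annotation.loc[vals.index, "length_bp"].to_numpy()
    keep = (nonzero_frac > min_nonzero_frac) & (lengths > min_length_bp)
    if not keep.any():
        raise ValueError(
            "no genes survive the expression/length filter; review thresholds"
        )
    return matrix._advance(vals.loc[keep], "expressed_filter")


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Classic quantile normalization: each column's values are replaced by
    the across-column mean of order statistics at their rank; tied values
    receive the mean of their tied ranks' reference values."""
    n, m = x.shape
    if m == 1:
        return x.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(np.int64) - 1
        hi = np.ceil(ranks).astype(np.int64) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return out


def log_quantile_normalize(matrix: ExpressionMatrix,
                           offset: float = LOG_OFFSET) -> ExpressionMatrix:
    """log10(x + offset), then quantile normalization across samples.

    A single-sample matrix is only log-transformed (normalization to the
    mean of one column is the identity).
    """
    matrix.require_stage("expressed_filter", "rpkm")
    logged = np.log10(matrix.values.to_numpy(dtype=float) + offset)
    normed = _quantile_normalize(logged)
    out = pd.DataFrame(normed, index=matrix.values.index, columns=matrix.values.columns)
    return matrix._advance(out, "log_qnorm")


def median_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples (applied twice in the
    pipeline: once after quantile normalization, once after batch removal)."""
    matrix.require_stage("log_qnorm", "batch_corrected")
    stage = "median_center" if matrix.stage == "log_qnorm" else "median_center_2"
    vals = matrix.values
    centred = vals.sub(vals.median(axis=1), axis=0)
    return matrix._advance(centred, stage)


# ---------------------------------------------------------------------------
# batch removal
# ---------------------------------------------------------------------------

def _sum_coding(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (effects) coding for one factor; first level is baseline."""
    levels = sorted(pd.unique(labels))
    k = len(levels)
    x = np.zeros((len(labels), max(k - 1, 0)))
    level_pos = {lv: i for i, lv in enumerate(levels)}
    for row, lv in enumerate(labels):
        i = level_pos[lv]
        if i == 0:
            x[row, :] = -1.0
        else:
            x[row, i - 1] = 1.0
    return x, levels


def remove_batch_effects(
    matrix: ExpressionMatrix,
    design: pd.DataFrame | None = None,
    factors: tuple[str, str] = ("culture_batch", "sequencing_batch"),
    method: str = "anova",
) -> ExpressionMatrix:
    """Remove additive culture- and sequencing-batch effects per gene.

    Fits value = grand mean + culture term + sequencing term by least
    squares on individual samples with sum-to-zero constraints, then
    subtracts the *centred* batch fit so each gene's grand mean is
    conserved exactly even under unbalanced designs.

    ``method="shrinkage"`` shrinks each factor's estimated level effects by
    a method-of-moments BLUP factor (a random-effects treatment of batch),
    instead of subtracting them fully.
    """
    matrix.require_stage("median_center")
    design = design if design is not None else matrix.design
    if design is None:
        raise ValueError("sample design with batch labels is required")
    vals = matrix.values
    design = design.loc[vals.columns]

    blocks, all_levels = [], []
    for f in factors:
        labels = design[f]
        counts = labels.value_counts()
        singles = counts[counts == 1]
        if len(singles):
            warnings.warn(
                f"batch factor '{f}' has single-sample level(s): {list(singles.index)}"
            )
        x, levels = _sum_coding(labels)
        blocks.append(x)
        all_levels.append(levels)

    x_full = np.column_stack([np.ones((len(design), 1))] + blocks)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError(
            "batch factors are confounded (aliased); cannot separate culture "
            "and sequencing batch effects"
        )

    y = vals.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(x_full, y, rcond=None)

    if method == "shrinkage":
        # shrink each factor's level effects toward zero by the BLUP factor
        # tau^2 / (tau^2 + sigma^2 / n_level), estimated by moments per gene
        resid = y - x_full @ beta
        dof = max(len(design) - x_full.shape[1], 1)
        sigma2 = (resid ** 2).sum(axis=0) / dof
        col = 1
        for f, levels in zip(factors, all_levels):
            k = len(levels)
            if k < 2:
                continue
            b = beta[col:col + k - 1]
            effects_full = np.vstack([-b.sum(axis=0, keepdims=True), b])  # k x genes
            n_bar = design[f].value_counts().reindex(levels).to_numpy().mean()
            tau2 = np.maximum(effects_full.var(axis=0, ddof=1) - sigma2 / n_bar, 0.0)
            shrink = tau2 / (tau2 + sigma2 / n_bar + 1e-300)
            beta[col:col + k - 1] = b * shrink[None, :]
            col += k - 1
    elif method != "anova":
        raise ValueError(f"unknown batch-removal method '{method}'")

    batch_fit = x_full[:, 1:] @ beta[1:]          # samples x genes
    batch_fit -= batch_fit.mean(axis=0, keepdims=True)  # conserve grand means
    corrected = (y - batch_fit).T
    out = pd.DataFrame(corrected, index=vals.index, columns=vals.columns)
    return matrix._advance(out, "batch_corrected")


def batch_variance_fraction(values: pd.DataFrame, design: pd.DataFrame,
                            factor: str) -> float:
    """Mean (over genes) fraction of total variance explained by a batch
    factor: SS_between / SS_total from level means."""
    design = design.loc[values.columns]
    x = values.to_numpy(dtype=float)
    grand = x.mean(axis=1, keepdims=True)
    ss_total = ((x - grand) ** 2).sum(axis=1)
    ss_between = np.zeros(len(values))
    for lv, cols in design.groupby(factor).groups.items():
        pos = values.columns.get_indexer(cols)
        level_mean = x[:, pos].mean(axis=1)
        ss_between += len(pos) * (level_mean - grand[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = ss_between / ss_total
    return float(np.nanmean(frac))


# ---------------------------------------------------------------------------

def variability_filter(matrix: ExpressionMatrix, min_sd: float = 0.1) -> ExpressionMatrix:
    """Keep genes whose across-sample s.d. (n-1 denominator) strictly
    exceeds ``min_sd``; boundary values are removed."""
    matrix.require_stage("median_center_2")
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > min_sd
    if not keep.any():
        raise ValueError("no genes survive the variability filter")
    return matrix._advance(vals.loc[keep], "sd_filter")


def combine_replicates(matrix: ExpressionMatrix,
                       design: pd.DataFrame | None = None) -> ChemicalProfileMatrix:
    """Collapse replicate samples to one column per chemical by the
    element-wise median; the vehicle is combined the same way and kept as a
    column."""
    matrix.require_stage("sd_filter")
    design = design if design is not None else matrix.design
    if design is None:
        raise ValueError("sample design is required to group replicates")
    design = design.loc[matrix.values.columns]
    groups = design.groupby("chemical").groups
    empty = [c for c, cols in groups.items() if len(cols) == 0]
    if empty:
        raise ValueError(f"chemical(s) with zero samples: {empty}")
    cols = {}
    for chem in sorted(groups):
        pos = matrix.values.columns.get_indexer(groups[chem])
        cols[chem] = np.median(matrix.values.to_numpy()[:, pos], axis=1)
    profiles = pd.DataFrame(cols, index=matrix.values.index)
    vehicle = None
    if "is_vehicle" in design.columns and design["is_vehicle"].any():
        vehicle = design.loc[design["is_vehicle"], "chemical"].iloc[0]
    return ChemicalProfileMatrix(
        values=profiles,
        provenance=matrix.provenance + ["combine_replicates"],
        retained_gene_ids=list(matrix.values.index),
        vehicle=vehicle,
    )


def preprocess_pipeline(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    log_offset: float = LOG_OFFSET,
    min_sd: float = 0.1,
    batch_method: str = "anova",
) -> ChemicalProfileMatrix:
    """Run the full prescribed preprocessing chain on a count matrix."""
    m = as_expression_matrix(counts, annotation=annotation, design=design)
    m = compute_rpkm(m)
    m = filter_expressed_genes(m)
    m = log_quantile_normalize(m, offset=log_offset)
    m = median_center_genes(m)
    m = remove_batch_effects(m, method=batch_method)
    m = median_center_genes(m)
    m = variability_filter(m, min_sd=min_sd)
    return combine_replicates(m)
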