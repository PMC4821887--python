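"""Seeded synthetic chemical screens with planted structure.

Emulates the layout of a cortical-culture chemical perturbation screen:
~300 chemicals at a single sub-cytotoxic concentration, 1-4 replicates each,
a DMSO vehicle condition with many replicates, culture and sequencing
batches, planted chemical classes that share transcriptional signatures,
class-specific depletion of mitochondrially encoded reads, and gene lengths
straddling the 500 bp expression-filter and 100 kb long-gene thresholds.
Every generator is a pure function of a :class:`SyntheticConfig`, so the
same config reproduces the same screen byte for byte.

The generative model for counts is deliberately simple so that downstream
recovery has an analytic oracle: log10 expected concentration is
``baseline + class effect + culture-batch effect + sequencing-batch effect
+ N(0, noise_sd)``; expected reads are proportional to concentration x
gene length, rescaled per sample to the configured depth; counts are
Poisson (optionally Gamma-Poisson when ``overdispersion > 0``).
Mitochondrial gene means are multiplied by the class's depletion factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gsa import GeneSet

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "PlantedTruth",
    "ToxicityProfile",
    "tiny_config",
    "default_config",
    "generate_annotation",
    "generate_design",
    "simulate_counts",
    "build_gene_sets",
    "simulate_cytotox_plate",
    "simulate_assay_table",
    "simulate_screen",
]

VEHICLE_LABEL = "vehicle"

# rng stream tags so each generator draws from an independent, reproducible stream
_RNG_ANNOTATION = 1
_RNG_DESIGN = 2
_RNG_COUNTS = 3
_RNG_GENESETS = 4
_RNG_CYTOTOX = 5
_RNG_ASSAYS = 6


class ConfigError(ValueError):
    """Raised when a synthetic-screen configuration is invalid."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic screen.

    Effect sizes, batch effects and noise are all on the log10 expression
    scale. ``mito_depletion`` maps a planted class id to a multiplier in
    (0, 1] applied to mitochondrial gene means for that class's samples.
    """

    n_genes: int = 12000
    n_chemicals: int = 300
    n_classes: int = 6
    chemicals_per_class: int = 8
    replicates: int = 4
    n_vehicle_replicates: int = 49
    screen_concentration_um: float = 10.0

    n_mito_genes: int = 37
    frac_short_genes: float = 0.10   # genes with length <= 500 bp
    frac_long_genes: float = 0.05    # genes with length > 100 kb

    signature_genes_per_class: int = 2000
    effect_size_range: tuple[float, float] = (0.3, 0.7)
    signature_baseline_range: tuple[float, float] = (0.55, 2.3)
    reserved_baseline_range: tuple[float, float] = (0.4, 2.4)

    n_culture_batches: int = 8
    n_sequencing_batches: int = 6
    batch_sd: float = 0.1
    batch_confounding: float = 0.0

    noise_sd: float = 0.15
    sequencing_depth: float = 6.0e6
    overdispersion: float = 0.0
    mito_depletion: Mapping[int, float] = field(default_factory=lambda: {1: 0.5})

    # weak group: an extra planted group whose members correlate with each
    # other above the Spearman membership threshold yet sit closer, in
    # average-linkage distance, to a strong class than to each other.
    # Satellites are Pearson-attached decoys in the strong class's branch
    # that fail Spearman membership; see docs/methods.md for the geometry.
    weak_group_enabled: bool = False
    weak_group_size: int = 5
    n_satellites: int = 6
    weak_anchor_class: int = 1
    weak_diffuse_genes: int = 700
    weak_diffuse_range: tuple[float, float] = (0.3, 0.7)
    outlier_block_genes: int = 380
    satellite_block_genes: int = 400
    outlier_effect: float = 1.0
    weak_outlier_scale: float = 2.4
    satellite_outlier_scale: float = 2.4
    # mild anti-correlation of weak members/satellites with the anchor
    # class's diffuse signature keeps their rank (Spearman) similarity to
    # the anchor safely below the membership threshold while leaving the
    # block-driven Pearson attraction nearly untouched
    weak_anti_genes: int = 600
    weak_anti_scale: float = 0.45
    # low-amplitude diffuse component shared by all satellites: speeds up
    # their chain attachment to the anchor branch without lifting their
    # mutual rank correlation near the membership threshold
    satellite_diffuse_genes: int = 250

    # every chemical additionally perturbs a private set of idiosyncratic
    # strong-responder genes; keeping this load uniform across chemicals
    # stops heavy-tailed profiles from sharing quantile-normalization
    # artefacts (weak members, satellites and the anchor class carry their
    # outlier blocks instead of a private load). Privates are drawn from
    # moderately expressed genes so they stay rank-extreme without eating
    # a meaningful share of the library.
    private_outlier_genes: int = 300
    private_outlier_effect: float = 1.2
    private_baseline_range: tuple[float, float] = (0.6, 1.4)

    # live/dead plates
    wells_per_condition: int = 4
    cells_per_well: int = 2000
    vehicle_dead_frac: float = 0.05

    # AC50 assay tables
    n_assays: int = 30
    assay_missing_rate: float = 0.0
    assay_active_rate: float = 0.15
    assay_inactive_ac50: float = 1000.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_chemicals <= 0:
            raise ConfigError("n_chemicals must be positive")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.n_vehicle_replicates < 1:
            raise ConfigError("n_vehicle_replicates must be >= 1")
        if self.n_classes < 0:
            raise ConfigError("n_classes must be >= 0")
        n_planted = self.n_classes * self.chemicals_per_class
        if self.weak_group_enabled:
            n_planted += self.weak_group_size + self.n_satellites
            if self.n_classes < 1:
                raise ConfigError("weak group requires at least one planted class")
        if n_planted > self.n_chemicals:
            raise ConfigError(
                f"planted chemicals ({n_planted}) exceed n_chemicals ({self.n_chemicals})"
            )
        lo, hi = self.effect_size_range
        if lo > hi:
            raise ConfigError("effect_size_range low must be <= high")
        if not (0 <= self.frac_short_genes and 0 <= self.frac_long_genes
                and self.frac_short_genes + self.frac_long_genes <= 1):
            raise ConfigError("gene length fractions must lie in [0,1] and sum to <= 1")
        if self.n_mito_genes < 0 or self.n_mito_genes > self.n_genes:
            raise ConfigError("n_mito_genes out of range")
        for cls, m in self.mito_depletion.items():
            if not (0 < m <= 1):
                raise ConfigError(f"mito_depletion for class {cls} must be in (0, 1]")
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing_depth must be positive")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Desk-scale default: 300 chemicals x 4 replicates x 12k genes."""
    cfg = replace(SyntheticConfig(), seed=seed, **overrides)
    cfg.validate()
    return cfg


def tiny_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Small preset (30 chemicals x 2k genes) for fast test runs."""
    base = SyntheticConfig(
        n_genes=2000,
        n_chemicals=30,
        n_classes=3,
        chemicals_per_class=5,
        replicates=2,
        n_vehicle_replicates=8,
        n_mito_genes=13,
        signature_genes_per_class=300,
        signature_baseline_range=(0.6, 2.2),
        n_culture_batches=3,
        n_sequencing_batches=2,
        sequencing_depth=1.0e6,
        weak_group_size=4,
        n_satellites=4,
        weak_diffuse_genes=120,
        outlier_block_genes=60,
        satellite_block_genes=65,
        satellite_diffuse_genes=40,
        weak_anti_genes=100,
        private_outlier_genes=50,
        n_assays=12,
    )
    cfg = replace(base, seed=seed, **overrides)
    cfg.validate()
    return cfg


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic screen.

    ``class_of_chemical`` maps every chemical to a class id (0 = inert).
    When the weak group is enabled, the weak group carries id
    ``n_classes + 1`` and satellites ``n_classes + 2``; neither is expected
    to survive the full discovery pipeline. ``member_signatures`` holds
    per-chemical effects for weak-group members and satellites, which are
    heterogeneous within their group by construction.
    """

    class_of_chemical: dict[str, int]
    signature_genes: dict[int, list[tuple[str, float]]]
    member_signatures: dict[str, list[tuple[str, float]]]
    mito_depletion: dict[int, float]
    culture_batch_effects: pd.DataFrame   # genes x culture-batch levels
    sequencing_batch_effects: pd.DataFrame
    weak_class_id: int | None = None
    satellite_class_id: int | None = None

    def members(self, class_id: int) -> list[str]:
        return sorted(c for c, k in self.class_of_chemical.items() if k == class_id)

    def effect_for(self, chemical: str) -> dict[str, float]:
        """Total planted log10 effect per gene for one chemical."""
        out: dict[str, float] = {}
        cls = self.class_of_chemical.get(chemical, 0)
        for g, e in self.signature_genes.get(cls, []):
            out[g] = out.get(g, 0.0) + e
        for g, e in self.member_signatures.get(chemical, []):
            out[g] = out.get(g, 0.0) + e
        return out


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), tag])


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SyntheticConfig) -> pd.DataFrame:
    """Gene annotation table: length_bp, is_mitochondrial, baseline_log10_expr.

    Lengths are drawn in three strata so that configured fractions fall at
    or below 500 bp and above 100 kb; the bulk is log-normal around a few
    kilobases. Mitochondrial genes (default 37) are short, highly expressed
    transcripts.
    """
    config.validate()
    rng = _rng(config, _RNG_ANNOTATION)
    n = config.n_genes
    n_mito = config.n_mito_genes
    n_nuc = n - n_mito

    gene_ids = [f"g{i:05d}" for i in range(n_nuc)] + [f"mt-g{i:02d}" for i in range(n_mito)]

    stratum = rng.choice(
        3, size=n_nuc,
        p=[config.frac_short_genes,
           1.0 - config.frac_short_genes - config.frac_long_genes,
           config.frac_long_genes],
    )
    length = np.empty(n_nuc, dtype=np.int64)
    short = stratum == 0
    mid = stratum == 1
    long_ = stratum == 2
    length[short] = rng.integers(100, 501, size=int(short.sum()))
    length[mid] = np.clip(
        np.round(10 ** rng.normal(3.4, 0.45, size=int(mid.sum()))), 501, 100_000
    ).astype(np.int64)
    length[long_] = np.round(
        10 ** rng.uniform(np.log10(100_001), 6.0, size=int(long_.sum()))
    ).astype(np.int64)

    mito_length = rng.integers(68, 1601, size=n_mito)
    baseline = rng.normal(0.7, 0.8, size=n_nuc)
    mito_baseline = rng.normal(2.5, 0.3, size=n_mito)

    ann = pd.DataFrame(
        {
            "length_bp": np.concatenate([length, mito_length]),
            "is_mitochondrial": np.concatenate(
                [np.zeros(n_nuc, dtype=bool), np.ones(n_mito, dtype=bool)]
            ),
            "baseline_log10_expr": np.concatenate([baseline, mito_baseline]),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# screen design and planted truth
# ---------------------------------------------------------------------------

def _draw_effects(rng: np.random.Generator, genes: Sequence[str],
                  lo: float, hi: float) -> list[tuple[str, float]]:
    mags = rng.uniform(lo, hi, size=len(genes))
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    return [(g, float(s * m)) for g, s, m in zip(genes, signs, mags)]


def generate_design(
    config: SyntheticConfig, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Sample layout plus planted ground truth.

    Chemicals are assigned to classes at random; the remainder stay inert.
    Culture and sequencing batches are assigned round-robin over a shuffled
    sample order, with an optional confounding fraction that copies the
    culture batch into the sequencing batch. Vehicle replicates are spread
    across batches the same way.
    """
    config.validate()
    if config.replicates < 1:
        raise ConfigError("replicates must be >= 1")
    rng = _rng(config, _RNG_DESIGN)

    chemicals = [f"chem{i + 1:04d}" for i in range(config.n_chemicals)]
    order = rng.permutation(config.n_chemicals)

    class_of: dict[str, int] = {c: 0 for c in chemicals}
    pos = 0
    for k in range(1, config.n_classes + 1):
        for _ in range(config.chemicals_per_class):
            class_of[chemicals[order[pos]]] = k
            pos += 1
    weak_id = sat_id = None
    if config.weak_group_enabled:
        weak_id = config.n_classes + 1
        sat_id = config.n_classes + 2
        for _ in range(config.weak_group_size):
            class_of[chemicals[order[pos]]] = weak_id
            pos += 1
        for _ in range(config.n_satellites):
            class_of[chemicals[order[pos]]] = sat_id
            pos += 1

    # signature genes: well-expressed, long enough to survive the length
    # filter, and disjoint from the mitochondrial genome
    def _eligible(lo: float, hi: float) -> np.ndarray:
        return annotation.index[
            (~annotation["is_mitochondrial"])
            & (annotation["length_bp"] > 500)
            & (annotation["baseline_log10_expr"].between(lo, hi))
        ].to_numpy()

    eligible = _eligible(*config.signature_baseline_range)
    eligible_wide = _eligible(*config.reserved_baseline_range)
    lo, hi = config.effect_size_range
    per_class = config.signature_genes_per_class
    n_reserved = 0
    if config.weak_group_enabled:
        n_sat_blocks = (config.n_satellites + 1) // 2
        n_reserved = (
            config.weak_diffuse_genes
            + config.weak_group_size * config.outlier_block_genes
            + n_sat_blocks * config.satellite_block_genes
            + config.satellite_diffuse_genes
            + 30 * config.n_satellites
        )
    if n_reserved > len(eligible_wide):
        raise ConfigError(
            f"not enough eligible genes ({len(eligible_wide)}) for "
            f"{n_reserved} weak-group genes"
        )
    # a dedicated disjoint pool for the weak-group construction; class
    # signatures are drawn independently per class from the remainder, so
    # different classes may overlap (independent effects per class)
    reserved = rng.choice(eligible_wide, size=n_reserved, replace=False)
    pool = np.setdiff1d(eligible, reserved)
    if per_class > len(pool):
        raise ConfigError(
            f"not enough eligible genes ({len(pool)}) for "
            f"{per_class} signature genes per class"
        )
    signature: dict[int, list[tuple[str, float]]] = {0: []}
    for k in range(1, config.n_classes + 1):
        genes = rng.choice(pool, size=per_class, replace=False)
        signature[k] = _draw_effects(rng, genes, lo, hi)

    member_signatures: dict[str, list[tuple[str, float]]] = {}
    if config.weak_group_enabled:
        anchor = config.weak_anchor_class
        cursor = 0
        wlo, whi = config.weak_diffuse_range

        def take_block(size: int) -> list[tuple[str, float]]:
            # each block joins the anchor class's signature at unit amplitude
            nonlocal cursor
            genes = reserved[cursor:cursor + size]
            cursor += size
            eff = _draw_effects(rng, genes, config.outlier_effect, config.outlier_effect)
            signature[anchor] = signature[anchor] + eff
            return eff

        weak_diffuse = _draw_effects(
            rng, reserved[cursor:cursor + config.weak_diffuse_genes], wlo, whi
        )
        cursor += config.weak_diffuse_genes
        anti = [
            (g, -config.weak_anti_scale * e)
            for g, e in signature[anchor][: config.weak_anti_genes]
        ]
        weak_members = sorted(c for c, k in class_of.items() if k == weak_id)
        for chem in weak_members:
            block = take_block(config.outlier_block_genes)
            own_block = [(g, e * config.weak_outlier_scale) for g, e in block]
            member_signatures[chem] = weak_diffuse + own_block + anti
        # satellites share their anchor blocks in pairs at most, so no
        # three of them can ever clear the pairwise-Spearman membership rule
        satellites = sorted(c for c, k in class_of.items() if k == sat_id)
        sat_blocks = [take_block(config.satellite_block_genes)
                      for _ in range((config.n_satellites + 1) // 2)]
        sat_diffuse = _draw_effects(
            rng, reserved[cursor:cursor + config.satellite_diffuse_genes], wlo, whi
        )
        cursor += config.satellite_diffuse_genes
        for i, chem in enumerate(satellites):
            block = sat_blocks[i // 2]
            sat_block = [(g, e * config.satellite_outlier_scale) for g, e in block]
            own = _draw_effects(rng, reserved[cursor:cursor + 30], wlo, whi)
            cursor += 30
            member_signatures[chem] = sat_block + sat_diffuse + own + anti

    # private idiosyncratic outliers, one equal-sized load per chemical;
    # chemicals whose planted profile already carries an outlier block
    # (weak members, satellites, anchor-class members) are skipped
    if config.private_outlier_genes > 0:
        plo, phi = config.private_baseline_range
        priv_pool = np.intersect1d(
            pool,
            annotation.index[
                annotation["baseline_log10_expr"].between(plo, phi)
            ].to_numpy(),
        )
        if len(priv_pool) < config.private_outlier_genes:
            raise ConfigError("not enough genes for private outlier draws")
        skip: set[str] = set()
        if config.weak_group_enabled:
            skip |= {c for c, k in class_of.items()
                     if k in (weak_id, sat_id, config.weak_anchor_class)}
        for chem in chemicals:
            if chem in skip:
                continue
            genes = rng.choice(priv_pool, size=config.private_outlier_genes, replace=False)
            priv = _draw_effects(
                rng, genes, config.private_outlier_effect, config.private_outlier_effect
            )
            member_signatures[chem] = member_signatures.get(chem, []) + priv

    # samples
    rows = []
    for chem in chemicals:
        for r in range(1, config.replicates + 1):
            rows.append((f"{chem}_r{r}", chem, config.screen_concentration_um, r, False))
    for r in range(1, config.n_vehicle_replicates + 1):
        rows.append((f"{VEHICLE_LABEL}_r{r}", VEHICLE_LABEL, 0.0, r, True))
    design = pd.DataFrame(
        rows, columns=["sample_id", "chemical", "concentration_um", "replicate", "is_vehicle"]
    ).set_index("sample_id")

    n_samples = len(design)
    culture = np.empty(n_samples, dtype=np.int64)
    seqb = np.empty(n_samples, dtype=np.int64)
    culture[rng.permutation(n_samples)] = np.arange(n_samples) % config.n_culture_batches
    seqb[rng.permutation(n_samples)] = np.arange(n_samples) % config.n_sequencing_batches
    confound = rng.random(n_samples) < config.batch_confounding
    seqb[confound] = culture[confound] % config.n_sequencing_batches
    design["culture_batch"] = [f"cb{i}" for i in culture]
    design["sequencing_batch"] = [f"sb{i}" for i in seqb]

    cb_levels = sorted(design["culture_batch"].unique())
    sb_levels = sorted(design["sequencing_batch"].unique())
    cb_eff = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, size=(len(annotation), len(cb_levels))),
        index=annotation.index, columns=cb_levels,
    )
    sb_eff = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, size=(len(annotation), len(sb_levels))),
        index=annotation.index, columns=sb_levels,
    )

    truth = PlantedTruth(
        class_of_chemical=class_of,
        signature_genes=signature,
        member_signatures=member_signatures,
        mito_depletion=dict(config.mito_depletion),
        culture_batch_effects=cb_eff,
        sequencing_batch_effects=sb_eff,
        weak_class_id=weak_id,
        satellite_class_id=sat_id,
    )
    return design, truth


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    truth: PlantedTruth,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Poisson (or Gamma-Poisson) read counts, genes x samples.

    Expected reads per gene are proportional to 10**log10mean x length_bp
    and each sample's expectation is rescaled to ``sequencing_depth``, so
    recomputed RPKM recovers the planted log10 effects.
    """
    config.validate()
    genes = annotation.index
    samples = design.index
    if truth.culture_batch_effects.shape[0] != len(genes):
        raise ConfigError("annotation and planted truth disagree on gene count")

    rng = _rng(config, _RNG_COUNTS)
    gene_pos = {g: i for i, g in enumerate(genes)}

    base = annotation["baseline_log10_expr"].to_numpy()
    log10m = np.tile(base[:, None], (1, len(samples)))

    # planted chemical effects
    effect_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, sid in enumerate(samples):
        chem = design.loc[sid, "chemical"]
        if chem not in effect_cache:
            eff = truth.effect_for(chem)
            idx = np.fromiter((gene_pos[g] for g in eff), dtype=np.int64, count=len(eff))
            val = np.fromiter(eff.values(), dtype=np.float64, count=len(eff))
            effect_cache[chem] = (idx, val)
        idx, val = effect_cache[chem]
        if len(idx):
            log10m[idx, j] += val

    cb = design["culture_batch"].to_numpy()
    sb = design["sequencing_batch"].to_numpy()
    log10m += truth.culture_batch_effects.loc[:, cb].to_numpy()
    log10m += truth.sequencing_batch_effects.loc[:, sb].to_numpy()

    if config.noise_sd > 0:
        log10m += rng.normal(0.0, config.noise_sd, size=log10m.shape)

    mito = annotation["is_mitochondrial"].to_numpy()
    if mito.any() and truth.mito_depletion:
        for j, sid in enumerate(samples):
            cls = truth.class_of_chemical.get(design.loc[sid, "chemical"], 0)
            mult = truth.mito_depletion.get(cls)
            if mult is not None and mult != 1.0:
                log10m[mito, j] += np.log10(mult)

    lam = 10.0 ** log10m * annotation["length_bp"].to_numpy()[:, None]
    lam *= config.sequencing_depth / lam.sum(axis=0, keepdims=True)
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = lam * rng.gamma(shape, scale=1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=samples)


def simulate_screen(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth, pd.DataFrame]:
    """Convenience wrapper: annotation, design, truth, counts."""
    ann = generate_annotation(config)
    design, truth = generate_design(config, ann)
    counts = simulate_counts(ann, design, truth, config)
    return ann, design, truth, counts


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def build_gene_sets(
    truth: PlantedTruth,
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    overlap_rate: float = 1.0,
    n_null_sets: int = 50,
    min_size: int = 10,
    max_size: int = 1500,
) -> list[GeneSet]:
    """Per planted class, an "up" and a "down" set overlapping its signature
    at ``overlap_rate``, plus random null sets. Sizes are clipped into the
    analysis window with a warning."""
    if not (0 < overlap_rate <= 1):
        raise ConfigError("overlap_rate must be in (0, 1]")
    rng = _rng(config, _RNG_GENESETS)
    all_genes = annotation.index.to_numpy()
    sets: list[GeneSet] = []

    def _clip(genes: list[str], name: str) -> list[str]:
        if len(genes) > max_size:
            warnings.warn(f"gene set {name} exceeds {max_size} genes; clipped")
            return list(rng.choice(genes, size=max_size, replace=False))
        if len(genes) < min_size:
            warnings.warn(f"gene set {name} below {min_size} genes; padded")
            pool = np.setdiff1d(all_genes, genes, assume_unique=False)
            pad = rng.choice(pool, size=min_size - len(genes), replace=False)
            return genes + list(pad)
        return genes

    for cls in sorted(truth.signature_genes):
        if cls == 0 or not truth.signature_genes[cls]:
            continue
        for tag, keep in (("up", lambda e: e > 0), ("down", lambda e: e < 0)):
            sig = [g for g, e in truth.signature_genes[cls] if keep(e)]
            if not sig:
                continue
            n_sig = max(1, int(round(len(sig) * overlap_rate)))
            core = list(rng.choice(sig, size=n_sig, replace=False)) if n_sig < len(sig) else list(sig)
            n_fill = int(round(len(core) * (1.0 - overlap_rate) / overlap_rate))
            pool = np.setdiff1d(all_genes, np.asarray(sig))
            fill = list(rng.choice(pool, size=n_fill, replace=False)) if n_fill else []
            name = f"class{cls}_{tag}"
            genes = _clip(core + fill, name)
            sets.append(GeneSet(name=name, genes=tuple(genes), direction=tag,
                                note=f"planted class {cls} signature ({tag})"))

    for i in range(n_null_sets):
        size = int(np.clip(round(10 ** rng.uniform(1.0, 2.7)), min_size, max_size))
        genes = rng.choice(all_genes, size=size, replace=False)
        sets.append(GeneSet(name=f"null{i + 1:03d}", genes=tuple(genes),
                            direction=None, note="random null set"))
    return sets


# ---------------------------------------------------------------------------
# live/dead plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToxicityProfile:
    """Hill-type dose-response for the dead-cell fraction of one chemical."""

    ec50_um: float
    max_dead_frac: float = 0.9
    hill: float = 2.0

    def dead_frac(self, dose_um: float, base: float) -> float:
        if dose_um <= 0:
            return base
        x = dose_um ** self.hill
        k = self.ec50_um ** self.hill
        return base + (self.max_dead_frac - base) * x / (x + k)


def simulate_cytotox_plate(
    toxicity: Mapping[str, ToxicityProfile | None],
    config: SyntheticConfig,
    doses_um: Mapping[str, Sequence[float]] | Sequence[float] = (10.0,),
) -> pd.DataFrame:
    """Live/dead plate counts in quadruplicate wells per chemical x dose.

    ``toxicity`` maps chemical -> dose-response (None = benign). Vehicle
    wells are emitted once per plate with the configured background dead
    fraction, kept below the 10% quality bar in expectation.
    """
    config.validate()
    rng = _rng(config, _RNG_CYTOTOX)
    rows = []
    well = 0

    def emit(chem: str, dose: float, p: float) -> None:
        nonlocal well
        for _ in range(config.wells_per_condition):
            total = int(rng.poisson(config.cells_per_well))
            total = max(total, 1)
            dead = int(rng.binomial(total, min(max(p, 0.0), 1.0)))
            rows.append((f"w{well:04d}", chem, dose, total, dead))
            well += 1

    emit(VEHICLE_LABEL, 0.0, config.vehicle_dead_frac)
    for chem in sorted(toxicity):
        chem_doses = (
            doses_um[chem] if isinstance(doses_um, Mapping) else doses_um
        )
        prof = toxicity[chem]
        for dose in chem_doses:
            p = (
                config.vehicle_dead_frac
                if prof is None
                else prof.dead_frac(float(dose), config.vehicle_dead_frac)
            )
            emit(chem, float(dose), p)

    return pd.DataFrame(
        rows, columns=["well", "chemical", "concentration_um", "total_nuclei", "dead_nuclei"]
    ).set_index("well")


# ---------------------------------------------------------------------------
# AC50 assay tables
# ---------------------------------------------------------------------------

def simulate_assay_table(
    design: pd.DataFrame,
    config: SyntheticConfig,
    truth: PlantedTruth | None = None,
    class_linked: bool = False,
) -> pd.DataFrame:
    """Chemicals x assays AC50 matrix (uM) with configurable missingness.

    When ``class_linked`` and a truth is given, each assay responds to one
    planted class (members active at low AC50), so assay-derived groupings
    should agree with expression-derived clusters; otherwise activity is
    independent of the planted classes and agreement stays at chance.
    """
    config.validate()
    rng = _rng(config, _RNG_ASSAYS)
    chemicals = sorted(c for c in design["chemical"].unique() if c != VEHICLE_LABEL)
    n_chem = len(chemicals)
    values = np.full((n_chem, config.n_assays), config.assay_inactive_ac50, dtype=float)

    if class_linked:
        if truth is None:
            raise ConfigError("class_linked assay table requires planted truth")
        n_classes = max(1, max((k for k in truth.signature_genes if k > 0), default=1))
        cls = np.array([truth.class_of_chemical.get(c, 0) for c in chemicals])
        for j in range(config.n_assays):
            target = (j % n_classes) + 1
            member = cls == target
            hit = member & (rng.random(n_chem) < 0.9)
            values[hit, j] = 10 ** rng.uniform(-2.0, 0.7, size=int(hit.sum()))
            stray = (~member) & (rng.random(n_chem) < 0.03)
            values[stray, j] = 10 ** rng.uniform(-1.0, 2.0, size=int(stray.sum()))
    else:
        for j in range(config.n_assays):
            hit = rng.random(n_chem) < config.assay_active_rate
            values[hit, j] = 10 ** rng.uniform(-2.0, 1.0, size=int(hit.sum()))

    if config.assay_missing_rate > 0:
        miss = rng.random(values.shape) < config.assay_missing_rate
        values[miss] = np.nan

    return pd.DataFrame(
        values, index=pd.Index(chemicals, name="chemical"),
        columns=[f"assay{j + 1:03d}" for j in range(config.n_assays)],
    )
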