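"""Per-chemical screening diagnostics.

Covers the screening-side arithmetic around the transcriptomic pipeline:
mitochondrial read fractions and their log2 fold change versus vehicle,
flagging of long (>100 kb) genes, live/dead percent-dead and the 10
percentage-point toxicity rule, the order-of-magnitude dose-reduction
search, Livak 2^-ddCt quantification, and corrected total cell
fluorescence for ROI measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MitoFractionRecord",
    "CytotoxRecord",
    "QpcrRecord",
    "RoiFluorescence",
    "mito_fraction_fc",
    "flag_long_genes",
    "percent_dead_and_toxicity",
    "find_noncytotoxic_concentration",
    "ddct_fold_change",
    "corrected_total_cell_fluorescence",
]

LONG_GENE_BP = 100_000
TOXICITY_THRESHOLD_PP = 10.0
DOSE_SEARCH_START_UM = 10.0
DOSE_SEARCH_FLOOR_UM = 1e-3  # 1 nM


@dataclass(frozen=True)
class MitoFractionRecord:
    chemical: str
    frac_mito_chemical: float
    frac_mito_vehicle: float
    log2_fc: float


@dataclass(frozen=True)
class CytotoxRecord:
    chemical: str
    concentration_um: float
    percent_dead_wells: tuple[float, ...]
    mean_percent_dead: float
    vehicle_mean_percent_dead: float
    excess_pp: float
    toxic: bool


@dataclass(frozen=True)
class QpcrRecord:
    target: str
    delta_ct_treated: float
    delta_ct_untreated: float
    delta_delta_ct: float
    fold_change: float


@dataclass(frozen=True)
class RoiFluorescence:
    roi_id: str
    integrated_density: float
    area: float
    mean_background: float
    corrected: float
    vehicle_normalized: float | None = None


# ---------------------------------------------------------------------------

def mito_fraction_fc(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    retained_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mitochondrial read fraction per chemical and its log2 fold change
    against vehicle.

    Fractions are computed from raw counts before any filtering; the
    per-chemical and vehicle fractions are means over replicate samples.
    When ``retained_genes`` (the clustering gene set) is supplied, the
    function checks that no mitochondrial gene slipped into it and warns
    otherwise.
    """
    mito = annotation.loc[counts.index, "is_mitochondrial"].to_numpy()
    if not mito.any():
        raise ValueError("annotation contains no mitochondrial genes")
    design = design.loc[counts.columns]
    if not design["is_vehicle"].any():
        raise ValueError("design contains no vehicle samples")

    if retained_genes is not None:
        leaked = set(annotation.index[annotation["is_mitochondrial"]]) & set(retained_genes)
        if leaked:
            warnings.warn(
                f"mitochondrial gene(s) present in the clustering gene set: {sorted(leaked)}"
            )

    totals = counts.sum(axis=0).to_numpy(dtype=float)
    mito_counts = counts.to_numpy()[mito].sum(axis=0)
    frac = pd.Series(mito_counts / totals, index=counts.columns)

    vehicle_frac = float(frac[design["is_vehicle"].to_numpy()].mean())
    if vehicle_frac == 0:
        raise ValueError("vehicle mitochondrial count is zero")

    rows = []
    for chem, cols in design[~design["is_vehicle"]].groupby("chemical").groups.items():
        f = float(frac[list(cols)].mean())
        rows.append(
            MitoFractionRecord(
                chemical=str(chem),
                frac_mito_chemical=f,
                frac_mito_vehicle=vehicle_frac,
                log2_fc=float(np.log2(f / vehicle_frac)) if f > 0 else float("-inf"),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("chemical").sort_index()


def flag_long_genes(annotation: pd.DataFrame, threshold_bp: int = LONG_GENE_BP) -> pd.Series:
    """Flag genes strictly longer than the threshold (default 100 kb)."""
    return annotation["length_bp"] > threshold_bp


# ---------------------------------------------------------------------------

def percent_dead_and_toxicity(
    plate: pd.DataFrame,
    threshold_pp: float = TOXICITY_THRESHOLD_PP,
    vehicle_label: str = "vehicle",
    mode: str = "vehicle_excess",
) -> list[CytotoxRecord]:
    """Percent-dead per well, replicate means, and the toxicity call.

    Default rule: a chemical x concentration is toxic when its mean
    percent-dead exceeds the vehicle mean by at least ``threshold_pp``
    percentage points (vehicle-subtracted). ``mode="absolute"`` instead
    compares the raw mean percent-dead to the threshold. With a ``plate``
    column present, vehicle means are taken per plate.
    """
    if mode not in ("vehicle_excess", "absolute"):
        raise ValueError(f"unknown toxicity mode '{mode}'")
    if (plate["total_nuclei"] <= 0).any():
        raise ValueError("wells must have total_nuclei > 0")
    df = plate.copy()
    df["percent_dead"] = 100.0 * df["dead_nuclei"] / df["total_nuclei"]

    plate_col = "plate" if "plate" in df.columns else None
    groups = df.groupby(plate_col) if plate_col else [(None, df)]

    records: list[CytotoxRecord] = []
    for _, sub in groups:
        veh = sub[sub["chemical"] == vehicle_label]
        if mode == "vehicle_excess" and veh.empty:
            raise ValueError("no vehicle wells on plate")
        veh_mean = float(veh["percent_dead"].mean()) if not veh.empty else 0.0
        chem_rows = sub[sub["chemical"] != vehicle_label]
        for (chem, dose), wells in chem_rows.groupby(["chemical", "concentration_um"]):
            pd_wells = tuple(float(v) for v in wells["percent_dead"])
            mean_pd = float(np.mean(pd_wells))
            if mode == "vehicle_excess":
                excess = mean_pd - veh_mean
            else:
                excess = mean_pd
            records.append(
                CytotoxRecord(
                    chemical=str(chem),
                    concentration_um=float(dose),
                    percent_dead_wells=pd_wells,
                    mean_percent_dead=mean_pd,
                    vehicle_mean_percent_dead=veh_mean,
                    excess_pp=float(excess),
                    toxic=bool(excess >= threshold_pp),
                )
            )
    return records


def find_noncytotoxic_concentration(
    is_toxic_at: Callable[[float], bool],
    start_um: float = DOSE_SEARCH_START_UM,
    reduction_factor: float = 10.0,
    floor_um: float = DOSE_SEARCH_FLOOR_UM,
    chemical: str | None = None,
) -> tuple[float, list[float]]:
    """First non-toxic dose in the sequence start, start/10, start/100, ...

    Returns the selected dose and the list of doses tested. Raises if the
    floor is reached while every tested dose is still toxic.
    """
    if reduction_factor <= 1:
        raise ValueError("reduction_factor must be > 1")
    tested: list[float] = []
    dose = float(start_um)
    while dose >= floor_um:
        tested.append(dose)
        if not is_toxic_at(dose):
            return dose, tested
        dose /= reduction_factor
    who = f" for {chemical}" if chemical else ""
    raise ValueError(
        f"no non-toxic dose found{who} down to {floor_um} uM (tested {tested})"
    )


# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct_target_treated: Sequence[float],
    ct_ref_treated: Sequence[float],
    ct_target_untreated: Sequence[float],
    ct_ref_untreated: Sequence[float],
    target: str = "",
) -> QpcrRecord:
    """Livak relative quantification: technical duplicates are averaged,
    dCt = mean Ct(target) - mean Ct(reference), ddCt = dCt(treated) -
    dCt(untreated), fold change = 2**(-ddCt)."""
    arrays = [np.asarray(a, dtype=float) for a in
              (ct_target_treated, ct_ref_treated, ct_target_untreated, ct_ref_untreated)]
    if any(not np.isfinite(a).all() for a in arrays):
        raise ValueError("Ct values must be finite")
    d_treated = arrays[0].mean() - arrays[1].mean()
    d_untreated = arrays[2].mean() - arrays[3].mean()
    ddct = d_treated - d_untreated
    return QpcrRecord(
        target=target,
        delta_ct_treated=float(d_treated),
        delta_ct_untreated=float(d_untreated),
        delta_delta_ct=float(ddct),
        fold_change=float(2.0 ** (-ddct)),
    )


def corrected_total_cell_fluorescence(
    integrated_density: float,
    area: float,
    mean_background: float,
    vehicle_mean: float | None = None,
    roi_id: str = "",
) -> RoiFluorescence:
    """Corrected total cell fluorescence of one ROI:
    corrected = integrated density - area x mean background, optionally
    normalized to the average corrected vehicle intensity."""
    if area <= 0:
        raise ValueError("ROI area must be positive")
    corrected = float(integrated_density) - float(area) * float(mean_background)
    normalized = None
    if vehicle_mean is not None:
        if vehicle_mean <= 0:
            raise ValueError("vehicle mean corrected intensity must be positive")
        normalized = corrected / float(vehicle_mean)
    return RoiFluorescence(
        roi_id=roi_id,
        integrated_density=float(integrated_density),
        area=float(area),
        mean_background=float(mean_background),
        corrected=corrected,
        vehicle_normalized=normalized,
    )
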