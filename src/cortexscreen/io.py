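"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts, annotation, design, plate and AC50 matrices travel as TSV; gene
set collections as standard GMT (name, description, tab-separated genes);
planted truth as JSON. Every writer round-trips through the matching
reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .gsa import GeneSet
from .synthetic import PlantedTruth

__all__ = [
    "write_counts_tsv", "read_counts_tsv",
    "write_annotation_tsv", "read_annotation_tsv",
    "write_design_tsv", "read_design_tsv",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_gmt", "read_gmt",
    "write_truth_json", "read_truth_json",
    "write_membership_tsv",
]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    ann["is_mitochondrial"] = ann["is_mitochondrial"].astype(bool)
    return ann


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col="sample_id")
    design["is_vehicle"] = design["is_vehicle"].astype(bool)
    for col in ("culture_batch", "sequencing_batch", "chemical"):
        if col in design.columns:
            design[col] = design[col].astype(str)
    return design


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path,
                     index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path, index_label: str = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_label)


# ---------------------------------------------------------------------------

def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            desc = gs.note or gs.direction or "na"
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, *genes = fields
            direction = desc if desc in ("up", "down") else None
            sets.append(GeneSet(name=name, genes=tuple(genes),
                                direction=direction, note=desc))
    return sets


# ---------------------------------------------------------------------------

def write_truth_json(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "class_of_chemical": truth.class_of_chemical,
        "signature_genes": {str(k): v for k, v in truth.signature_genes.items()},
        "member_signatures": truth.member_signatures,
        "mito_depletion": {str(k): v for k, v in truth.mito_depletion.items()},
        "culture_batch_effects": {
            "index": list(truth.culture_batch_effects.index),
            "columns": list(truth.culture_batch_effects.columns),
            "values": truth.culture_batch_effects.to_numpy().tolist(),
        },
        "sequencing_batch_effects": {
            "index": list(truth.sequencing_batch_effects.index),
            "columns": list(truth.sequencing_batch_effects.columns),
            "values": truth.sequencing_batch_effects.to_numpy().tolist(),
        },
        "weak_class_id": truth.weak_class_id,
        "satellite_class_id": truth.satellite_class_id,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth_json(path: str | Path) -> PlantedTruth:
    with open(path) as fh:
        payload = json.load(fh)

    def frame(block):
        return pd.DataFrame(
            block["values"],
            index=pd.Index(block["index"], name="gene_id"),
            columns=block["columns"],
        )

    return PlantedTruth(
        class_of_chemical=dict(payload["class_of_chemical"]),
        signature_genes={
            int(k): [(g, float(e)) for g, e in v]
            for k, v in payload["signature_genes"].items()
        },
        member_signatures={
            c: [(g, float(e)) for g, e in v]
            for c, v in payload["member_signatures"].items()
        },
        mito_depletion={int(k): float(v) for k, v in payload["mito_depletion"].items()},
        culture_batch_effects=frame(payload["culture_batch_effects"]),
        sequencing_batch_effects=frame(payload["sequencing_batch_effects"]),
        weak_class_id=payload.get("weak_class_id"),
        satellite_class_id=payload.get("satellite_class_id"),
    )


def write_membership_tsv(result, path: str | Path) -> None:
    """Chemical, cluster, per-cluster min Spearman and mean silhouette."""
    rows = []
    for k, cl in enumerate(result.final_clusters):
        rho = result.min_pairwise_spearman[k]
        try:
            idx = result.candidate_clusters.index(cl)
            sil = result.mean_silhouette[idx]
        except ValueError:
            sil = float("nan")
        for chem in cl:
            rows.append((chem, k, rho, sil))
    for chem, member in result.membership.items():
        if member is None:
            rows.append((chem, "unassigned", "", ""))
    pd.DataFrame(
        rows, columns=["chemical", "cluster", "min_pairwise_spearman", "mean_silhouette"]
    ).to_csv(path, sep="\t", index=False)
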