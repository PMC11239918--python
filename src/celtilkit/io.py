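"""Readers and writers for the tabular formats the pipeline consumes.

Everything is plain text: clinical/pathology tables (CSV/TSV),
genes x samples count matrices (TSV), SEG-format segmented copy number,
MAF-like somatic mutation tables, and the model files (subtype
centroids, signature weights, segment definitions, CN coefficient
matrix, CN cluster centroids).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from celtilkit.celtil import BiopsyAssessment
from celtilkit.copynumber import (
    CNSignatureModel,
    GeneAnnotation,
    SegmentProfile,
    SegmentRecord,
)
from celtilkit.variants import VariantRecord

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "t_alt_count",
    "t_depth",
    "gnomAD_AF",
]

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "seg.mean"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------- clinical


def read_clinical(path: str | Path) -> list[BiopsyAssessment]:
    """Clinical/pathology table with columns sample_id, timepoint,
    cellularity_pct, tils_pct (percentages on the 0–100 scale)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    required = {"sample_id", "timepoint", "cellularity_pct", "tils_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return [
        BiopsyAssessment(
            sample_id=str(row.sample_id),
            timepoint=str(row.timepoint),
            cellularity=float(row.cellularity_pct),
            tils=float(row.tils_pct),
        )
        for row in df.itertuples()
    ]


def write_clinical(assessments: Sequence[BiopsyAssessment], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assessments],
            "timepoint": [a.timepoint for a in assessments],
            "cellularity_pct": [a.cellularity for a in assessments],
            "tils_pct": [a.tils for a in assessments],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------- counts


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples count matrix, first column gene id."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(Path(path), sep="\t", index_label="gene")


# ---------------------------------------------------------------- SEG


def read_seg(path: str | Path) -> list[SegmentProfile]:
    """SEG file (ID, chrom, loc.start, loc.end, [num.mark,] seg.mean).

    Coordinates are taken as 1-based inclusive.
    """
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("id")
    mean_col = cols.get("seg.mean")
    if id_col is None or mean_col is None:
        raise ValueError("SEG file needs ID and seg.mean columns")
    profiles = []
    for sample, grp in df.groupby(id_col, sort=True):
        records = tuple(
            SegmentRecord(
                chromosome=str(row[cols["chrom"]]),
                start=int(row[cols["loc.start"]]),
                end=int(row[cols["loc.end"]]),
                cn_signal=float(row[mean_col]),
            )
            for _, row in grp.iterrows()
        )
        profiles.append(SegmentProfile(sample_id=str(sample), records=records))
    return profiles


def write_seg(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    rows = [
        {
            "ID": p.sample_id,
            "chrom": r.chromosome,
            "loc.start": r.start,
            "loc.end": r.end,
            "seg.mean": r.cn_signal,
        }
        for p in profiles
        for r in p.records
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------- MAF


def read_maf(path: str | Path) -> list[VariantRecord]:
    """MAF-like somatic mutation table; gnomAD_AF may be blank (missing)."""
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"MAF table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        depth = int(row.t_depth)
        alt = int(row.t_alt_count)
        pop_af = getattr(row, "gnomAD_AF")
        records.append(
            VariantRecord(
                sample_id=str(row.Tumor_Sample_Barcode),
                gene=str(row.Hugo_Symbol),
                chromosome=str(row.Chromosome),
                position=int(row.Start_Position),
                ref=str(row.Reference_Allele),
                alt=str(row.Tumor_Seq_Allele2),
                variant_class=str(row.Variant_Type),
                alt_reads=alt,
                depth=depth,
                vaf=alt / depth if depth else 0.0,
                population_af=None if pd.isna(pop_af) else float(pop_af),
            )
        )
    return records


def write_maf(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "Tumor_Sample_Barcode": r.sample_id,
            "Hugo_Symbol": r.gene,
            "Chromosome": r.chromosome,
            "Start_Position": r.position,
            "Reference_Allele": r.ref,
            "Tumor_Seq_Allele2": r.alt,
            "Variant_Type": r.variant_class,
            "t_alt_count": r.alt_reads,
            "t_depth": r.depth,
            "gnomAD_AF": "" if r.population_af is None else r.population_af,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------- models


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Subtype centroids TSV: first column gene, one column per subtype."""
    return pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")


def write_centroids(centroids: pd.DataFrame, path: str | Path) -> None:
    centroids.to_csv(Path(path), sep="\t", index_label="gene")


def read_signatures(path: str | Path) -> dict[str, dict[str, float]]:
    """Signature weights TSV with columns signature, gene, weight."""
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.signature), {})[str(row.gene)] = float(row.weight)
    return out


def write_signatures(signatures: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    rows = [
        {"signature": name, "gene": g, "weight": w}
        for name, weights in signatures.items()
        for g, w in weights.items()
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Gene annotation TSV (gene, chromosome, start, end) or 4-column BED
    (chrom, start0, end, gene; half-open converted to 1-based inclusive)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chromosome", "start", "end", "gene"],
            float_precision="round_trip",
        )
        df["start"] = df["start"] + 1  # BED is 0-based half-open
        df = df.set_index("gene")[["chromosome", "start", "end"]]
    else:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip").set_index("gene")[
            ["chromosome", "start", "end"]
        ]
    return GeneAnnotation(table=df)


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(Path(path), sep="\t", index_label="gene")


def read_segment_definitions(path: str | Path) -> dict[str, list[str]]:
    """Segment definitions TSV with columns segment, gene."""
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    out: dict[str, list[str]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.segment), []).append(str(row.gene))
    return out


def write_segment_definitions(defs: Mapping[str, Sequence[str]], path: str | Path) -> None:
    rows = [{"segment": s, "gene": g} for s, genes in defs.items() for g in genes]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_cn_model(coefficients_path: str | Path, centroids_path: str | Path) -> CNSignatureModel:
    """CN signature model from a signatures x segments coefficient TSV and
    a clusters x signatures centroid TSV."""
    coeff = pd.read_csv(Path(coefficients_path), sep="\t", index_col=0, float_precision="round_trip")
    centroids = pd.read_csv(Path(centroids_path), sep="\t", index_col=0, float_precision="round_trip")
    return CNSignatureModel(coefficients=coeff, centroids=centroids)


def write_cn_model(model: CNSignatureModel, coefficients_path: str | Path,
                   centroids_path: str | Path) -> None:
    model.coefficients.to_csv(Path(coefficients_path), sep="\t", index_label="signature")
    model.centroids.to_csv(Path(centroids_path), sep="\t", index_label="cluster")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
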