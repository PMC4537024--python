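"""Readers and writers for the tabular/interval formats the pipeline touches.

Formats: expression matrices and metadata as TSV; peaks as an 8-column
BED-plus TSV; annotation as TSV or GTF; classification reports as TSV with
a JSON sidecar of summary counts.
"""
from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    REPORT_FLAGS,
    ExpressionStudy,
    GeneAnnotation,
    GeneClassificationReport,
    Peak,
    SampleMeta,
)

__all__ = [
    "read_expression_study",
    "write_expression_study",
    "read_peaks",
    "write_peaks",
    "read_annotation",
    "write_annotation",
    "write_report",
    "read_report",
]

_PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "sample_id",
    "tags",
    "igg_tags",
    "sample_libsize",
    "igg_libsize",
]

_META_COLUMNS = [
    "sample_id",
    "cell_type",
    "donor_id",
    "treatment",
    "medium",
    "replicate_group",
]


def _read_matrix(path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value in {name} matrix at gene {row!r}, sample {col!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValueError(f"missing value in {name} matrix at gene {row!r}, sample {col!r}")
        df[col] = coerced
    return df


def read_expression_study(fpkm_path, tags_path, meta_path) -> ExpressionStudy:
    """Load a validated expression study from three TSV files.

    The matrices have gene_id as first column and sample_ids as header;
    the metadata table is keyed by sample_id.  Gene and sample order is
    preserved from the files.
    """
    fpkm = _read_matrix(fpkm_path, "fpkm")
    tags_raw = pd.read_csv(tags_path, sep="\t", index_col=0)
    for col in tags_raw.columns:
        coerced = pd.to_numeric(tags_raw[col], errors="coerce")
        if coerced.isna().any():
            row = tags_raw.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric value in tags matrix at gene {row!r}, sample {col!r}"
            )
        frac = coerced - np.floor(coerced)
        if (frac != 0).any():
            row = tags_raw.index[frac != 0][0]
            raise ValueError(
                f"non-integral tag count at gene {row!r}, sample {col!r}"
            )
        tags_raw[col] = coerced.astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing_cols = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")
    meta_ids = set(meta["sample_id"])
    mat_ids = set(fpkm.columns)
    if meta_ids != mat_ids:
        raise ValueError(
            "sample sets differ between metadata and matrices; "
            f"missing: {sorted(meta_ids - mat_ids)}; "
            f"extra: {sorted(mat_ids - meta_ids)}"
        )
    samples = [SampleMeta(**{c: row[c] for c in _META_COLUMNS}) for _, row in meta.iterrows()]
    return ExpressionStudy(fpkm=fpkm, tags=tags_raw, samples=samples)


def write_expression_study(study: ExpressionStudy, fpkm_path, tags_path, meta_path) -> None:
    study.fpkm.to_csv(fpkm_path, sep="\t", index_label="gene_id", float_format="%.6g")
    study.tags.to_csv(tags_path, sep="\t", index_label="gene_id")
    study.meta.to_csv(meta_path, sep="\t", index=False)


def read_peaks(bed_path) -> list[Peak]:
    """Read an 8-column BED-plus table of ChIP peaks.

    Intervals are taken verbatim as 0-based half-open; lines starting
    with '#' are skipped.
    """
    peaks: list[Peak] = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_PEAK_COLUMNS):
                raise ValueError(
                    f"{bed_path}:{ln}: expected {len(_PEAK_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                peaks.append(
                    Peak(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        sample_id=fields[3],
                        tags=int(fields[4]),
                        igg_tags=int(fields[5]),
                        sample_libsize=int(fields[6]),
                        igg_libsize=int(fields[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{ln}: {exc}") from exc
    return peaks


def write_peaks(peaks: list[Peak], bed_path) -> None:
    with open(bed_path, "w") as fh:
        fh.write("#" + "\t".join(_PEAK_COLUMNS) + "\n")
        for p in peaks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        p.chrom,
                        p.start,
                        p.end,
                        p.sample_id,
                        p.tags,
                        p.igg_tags,
                        p.sample_libsize,
                        p.igg_libsize,
                    )
                )
                + "\n"
            )


def _read_annotation_tsv(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    required = ["gene_id", "symbol", "chrom", "strand", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    return [
        GeneAnnotation(
            gene_id=row.gene_id,
            symbol=row.symbol,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss),
        )
        for row in df.itertuples()
    ]


def _read_annotation_gtf(path) -> list[GeneAnnotation]:
    # gene feature lines only; GTF is 1-based closed -> 0-based half-open.
    # TSS = start of the gene on '+', end on '-'.
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            chrom, _, _, start1, end1, _, strand = fields[:7]
            attrs = {}
            for part in fields[8].strip().split(";"):
                part = part.strip()
                if not part:
                    continue
                key, _, val = part.partition(" ")
                attrs[key] = val.strip('"')
            start0 = int(start1) - 1
            end0 = int(end1)  # closed -> half-open
            tss = start0 if strand == "+" else end0 - 1
            records.append(
                GeneAnnotation(
                    gene_id=attrs.get("gene_id", ""),
                    symbol=attrs.get("gene_name", attrs.get("gene_id", "")),
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                )
            )
    return records


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a TSS table (TSV) or derive TSS records from a GTF file."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        records = _read_annotation_gtf(path)
    else:
        records = _read_annotation_tsv(path)
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id in annotation: {rec.gene_id!r}")
        seen.add(rec.gene_id)
    return records


def write_annotation(records: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "symbol": [r.symbol for r in records],
            "chrom": [r.chrom for r in records],
            "strand": [r.strand for r in records],
            "tss": [r.tss for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_report(report: GeneClassificationReport, path) -> None:
    """Serialize a classification report as TSV (flags as 0/1, absent flags
    as empty cells) plus a ``<path>.summary.json`` sidecar of set sizes and
    pairwise intersections."""
    path = Path(path)
    df = report.table.copy()
    out = pd.DataFrame(index=df.index)
    for col in REPORT_FLAGS:
        out[col] = df[col].map({True: "1", False: "0"}).astype("string")
    out["fdr_q"] = df["fdr_q"].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out["median_logfc_tam_vs_mdm"] = df["median_logfc_tam_vs_mdm"].map(
        lambda v: "" if pd.isna(v) else f"{v:.6g}"
    )
    out.to_csv(path, sep="\t", index_label="gene_id", na_rep="")
    with open(str(path) + ".summary.json", "w") as fh:
        json.dump(report.summary_counts(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> GeneClassificationReport:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", dtype="string")
    table = pd.DataFrame(index=df.index)
    for col in REPORT_FLAGS:
        table[col] = df[col].map({"1": True, "0": False}).astype("boolean")
    for col in ("fdr_q", "median_logfc_tam_vs_mdm"):
        table[col] = pd.to_numeric(df[col], errors="coerce")
    return GeneClassificationReport(table=table)
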