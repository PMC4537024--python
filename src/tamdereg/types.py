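"""Domain types shared by every pipeline stage.

The pipeline operates on gene-level expression matrices (FPKM plus raw
deduplicated tag counts), ChIP enrichment intervals with matched IgG
control counts, and a TSS annotation.  All genomic coordinates are
0-based half-open throughout; GTF input is converted on read.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellType",
    "Treatment",
    "Medium",
    "SampleMeta",
    "ExpressionStudy",
    "GeneAnnotation",
    "Peak",
    "GeneClassificationReport",
    "REPORT_FLAGS",
]


class CellType(str, enum.Enum):
    MONOCYTE = "MONOCYTE"
    MDM = "MDM"
    TAM = "TAM"


class Treatment(str, enum.Enum):
    DMSO = "DMSO"
    AGONIST = "AGONIST"
    INVERSE_ST247 = "INVERSE_ST247"
    INVERSE_PTS264 = "INVERSE_PTS264"
    #: ex vivo exposure to malignant ascites (freshly isolated TAMs carry
    #: no experimental ligand treatment; the ascites itself is the stimulus)
    ASCITES = "ASCITES"


class Medium(str, enum.Enum):
    R10 = "R10"
    R0 = "R0"
    XV0 = "XV0"
    ASCITES = "ASCITES"


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-Seq sample.

    ``replicate_group`` pairs a treated sample with the DMSO control from
    the same donor so that fold changes can be computed pairwise per donor.
    """

    sample_id: str
    cell_type: CellType
    donor_id: str
    treatment: Treatment
    medium: Medium
    replicate_group: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_type", CellType(self.cell_type))
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        object.__setattr__(self, "medium", Medium(self.medium))


@dataclass(frozen=True)
class GeneAnnotation:
    """One TSS record per gene; coordinates 0-based."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"unknown strand {self.strand!r} for gene {self.gene_id}"
            )
        if self.tss < 0:
            raise ValueError(f"negative TSS for gene {self.gene_id}")


@dataclass(frozen=True)
class Peak:
    """A ChIP enrichment interval (0-based half-open) with deduplicated
    tag counts for the ChIP sample and its matched IgG control."""

    chrom: str
    start: int
    end: int
    sample_id: str
    tags: int
    igg_tags: int
    sample_libsize: int
    igg_libsize: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError("negative coordinate")
        if self.tags < 0 or self.igg_tags < 0:
            raise ValueError("negative tag count")
        if self.sample_libsize <= 0 or self.igg_libsize <= 0:
            raise ValueError("library sizes must be positive")


@dataclass
class ExpressionStudy:
    """Gene-level FPKM and tag-count matrices plus sample metadata.

    ``fpkm`` and ``tags`` are genes x samples DataFrames sharing index
    (gene_id) and columns (sample_id); ``samples`` preserves file order.
    """

    fpkm: pd.DataFrame
    tags: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        meta_ids = [s.sample_id for s in self.samples]
        if len(set(meta_ids)) != len(meta_ids):
            dup = sorted({x for x in meta_ids if meta_ids.count(x) > 1})
            raise ValueError(f"duplicate sample_id in metadata: {dup}")
        for name, df in (("fpkm", self.fpkm), ("tags", self.tags)):
            missing = sorted(set(meta_ids) - set(df.columns))
            extra = sorted(set(df.columns) - set(meta_ids))
            if missing or extra:
                raise ValueError(
                    f"sample mismatch between metadata and {name} matrix; "
                    f"missing: {missing}; extra: {extra}"
                )
        if not self.fpkm.index.equals(self.tags.index):
            raise ValueError("fpkm and tags matrices list different genes")
        if not np.isfinite(self.fpkm.to_numpy()).all():
            raise ValueError("non-finite FPKM value")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("negative FPKM value")
        t = self.tags.to_numpy()
        if not np.isfinite(t).all():
            raise ValueError("non-finite tag count")
        if (t < 0).any():
            raise ValueError("negative tag count")
        frac = t - np.floor(t)
        if (frac != 0).any():
            g, s = np.argwhere(frac != 0)[0]
            raise ValueError(
                f"non-integral tag count at gene {self.tags.index[g]!r}, "
                f"sample {self.tags.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "cell_type": [s.cell_type.value for s in self.samples],
                "donor_id": [s.donor_id for s in self.samples],
                "treatment": [s.treatment.value for s in self.samples],
                "medium": [s.medium.value for s in self.samples],
                "replicate_group": [s.replicate_group for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def select(self, **conditions) -> list[SampleMeta]:
        """Samples matching all given field values (enum or raw string)."""
        out = []
        for s in self.samples:
            ok = True
            for k, v in conditions.items():
                attr = getattr(s, k)
                val = attr.value if isinstance(attr, enum.Enum) else attr
                want = v.value if isinstance(v, enum.Enum) else v
                if val != want:
                    ok = False
                    break
            if ok:
                out.append(s)
        return out


#: boolean flags carried by a classification report, in output order
REPORT_FLAGS = [
    "expressed",
    "agonist_up_mdm",
    "inverse_down_mdm",
    "agonist_vs_inverse_up_mdm",
    "ligand_regulated",
    "peak_associated_mdm",
    "peak_associated_tam",
    "up_in_tam_vivo",
    "up_in_tam_vitro",
    "refractory_in_tam",
]


@dataclass
class GeneClassificationReport:
    """Per-gene boolean classification flags plus the per-gene FDR q-value
    and the TAM-vs-MDM median log2 fold change.

    Flags are stored in a DataFrame indexed by gene_id.  Columns listed in
    :data:`REPORT_FLAGS` are nullable booleans (a missing contrast leaves a
    flag absent, not False); ``fdr_q`` and ``median_logfc_tam_vs_mdm`` are
    floats (NaN when not computed).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in REPORT_FLAGS:
            if col not in df.columns:
                df[col] = pd.array([pd.NA] * len(df), dtype="boolean")
            else:
                df[col] = df[col].astype("boolean")
        for col in ("fdr_q", "median_logfc_tam_vs_mdm"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = df[col].astype(float)
        self.table = df
        self.validate()

    def validate(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            raise ValueError("duplicate gene_id in report")
        lig = df["ligand_regulated"]
        union = (
            df["agonist_up_mdm"].fillna(False)
            | df["inverse_down_mdm"].fillna(False)
            | df["agonist_vs_inverse_up_mdm"].fillna(False)
        )
        known = lig.notna()
        if not (lig[known].astype(bool) == union[known]).all():
            raise ValueError(
                "ligand_regulated must be the union of the three comparisons"
            )
        bad = df["refractory_in_tam"].fillna(False) & ~df["agonist_up_mdm"].fillna(False)
        if bad.any():
            raise ValueError(
                "refractory genes must be agonist-inducible in MDMs: "
                f"{list(df.index[bad])[:5]}"
            )
        q = df["fdr_q"].dropna()
        if ((q < 0) | (q > 1)).any():
            raise ValueError("fdr_q outside [0, 1]")

    def gene_set(self, flag: str) -> set[str]:
        col = self.table[flag]
        return set(self.table.index[col.fillna(False).astype(bool)])

    def summary_counts(self) -> dict[str, int]:
        """Sizes of every flag set and of selected pairwise intersections."""
        counts = {flag: len(self.gene_set(flag)) for flag in REPORT_FLAGS}
        pairs = [
            ("ligand_regulated", "peak_associated_mdm"),
            ("ligand_regulated", "peak_associated_tam"),
            ("peak_associated_mdm", "peak_associated_tam"),
            ("up_in_tam_vivo", "up_in_tam_vitro"),
            ("up_in_tam_vivo", "refractory_in_tam"),
            ("agonist_up_mdm", "inverse_down_mdm"),
            ("agonist_up_mdm", "agonist_vs_inverse_up_mdm"),
            ("inverse_down_mdm", "agonist_vs_inverse_up_mdm"),
        ]
        for a, b in pairs:
            counts[f"{a}&{b}"] = len(self.gene_set(a) & self.gene_set(b))
        counts["ligand_regulated&peak_any"] = len(
            self.gene_set("ligand_regulated")
            & (self.gene_set("peak_associated_mdm") | self.gene_set("peak_associated_tam"))
        )
        return counts
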