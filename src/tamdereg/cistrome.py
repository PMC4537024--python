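"""ChIP peak filtering, cross-sample reproducibility, peak-to-gene assignment.

Peaks pass an absolute tag filter and a library-size-normalized fold
change over the matched IgG control; reproducible enrichment sites are
single-linkage merges of overlapping peaks supported by a minimum number
of distinct samples; genes are associated to enrichment sites by a TSS
window (50 kb by default, inclusive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GeneAnnotation, GeneClassificationReport, Peak

__all__ = [
    "ConsensusPeak",
    "filter_peaks",
    "reproducible_peaks",
    "assign_genes",
    "intersect_with_targets",
]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusPeak:
    """Union span of overlap-connected peaks from >= min_samples samples."""

    chrom: str
    start: int
    end: int
    supporting_samples: set[str] = field(default_factory=set)
    member_peaks: list[Peak] = field(default_factory=list)


def normalized_fold_change(peak: Peak) -> float:
    """Library-size-normalized ChIP/IgG ratio with a pseudocount of one
    tag on the IgG side only (guards against zero-control division)."""
    chip = peak.tags / peak.sample_libsize
    ctrl = (peak.igg_tags + 1) / peak.igg_libsize
    return chip / ctrl


def filter_peaks(peaks: list[Peak], min_tags: int = 30, min_fc: float = 2.0) -> list[Peak]:
    """Keep peaks with tags >= min_tags and normalized FC over IgG >= min_fc
    (both inclusive)."""
    return [
        p for p in peaks if p.tags >= min_tags and normalized_fold_change(p) >= min_fc
    ]


def reproducible_peaks(
    peaks_by_sample: dict[str, list[Peak]], min_samples: int = 2
) -> list[ConsensusPeak]:
    """Single-linkage merge of intervals overlapping by >= 1 bp across
    samples; a consensus is kept iff supported by >= min_samples distinct
    samples.  Adjacent half-open intervals (end == start) do not overlap.
    """
    if min_samples > len(peaks_by_sample):
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({len(peaks_by_sample)})"
        )
    flat: list[Peak] = []
    for sample_peaks in peaks_by_sample.values():
        flat.extend(sample_peaks)
    by_chrom: dict[str, list[Peak]] = {}
    for p in flat:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: list[ConsensusPeak] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end, p.sample_id))
        current: ConsensusPeak | None = None
        for p in chrom_peaks:
            if current is not None and p.start < current.end:
                current.end = max(current.end, p.end)
                current.supporting_samples.add(p.sample_id)
                current.member_peaks.append(p)
            else:
                if current is not None:
                    out.append(current)
                current = ConsensusPeak(
                    chrom=chrom,
                    start=p.start,
                    end=p.end,
                    supporting_samples={p.sample_id},
                    member_peaks=[p],
                )
        if current is not None:
            out.append(current)
    return [c for c in out if len(c.supporting_samples) >= min_samples]


def _tss_peak_distance(tss: int, start: int, end: int) -> int:
    if start <= tss < end:
        return 0
    return min(abs(tss - start), abs(tss - (end - 1)))


def assign_genes(
    consensus: list[ConsensusPeak],
    annotation: list[GeneAnnotation],
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Flag genes whose TSS lies within window_bp (inclusive) of any
    consensus enrichment site.

    Returns a DataFrame indexed by gene_id with columns ``peak_associated``
    (bool) and ``nearest_peak_distance`` (bp; NaN when the chromosome has
    no peaks).  The distance is 0 for a TSS inside a peak, else the
    distance to the nearest retained base of the interval; strand is
    ignored.
    """
    peaks_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c.chrom for c in consensus}:
        members = sorted(
            (c for c in consensus if c.chrom == chrom), key=lambda c: c.start
        )
        starts = np.array([c.start for c in members], dtype=np.int64)
        ends = np.array([c.end for c in members], dtype=np.int64)
        peaks_by_chrom[chrom] = (starts, ends)

    missing_chroms = {c.chrom for c in consensus} - {a.chrom for a in annotation}
    if missing_chroms:
        logger.warning(
            "peaks on chromosomes absent from annotation: %s", sorted(missing_chroms)
        )

    gene_ids, flags, dists = [], [], []
    for gene in annotation:
        gene_ids.append(gene.gene_id)
        if gene.chrom not in peaks_by_chrom:
            flags.append(False)
            dists.append(np.nan)
            continue
        starts, ends = peaks_by_chrom[gene.chrom]
        inside = (starts <= gene.tss) & (gene.tss < ends)
        if inside.any():
            flags.append(True)
            dists.append(0.0)
            continue
        d = np.minimum(np.abs(gene.tss - starts), np.abs(gene.tss - (ends - 1))).min()
        flags.append(bool(d <= window_bp))
        dists.append(float(d))
    return pd.DataFrame(
        {"peak_associated": flags, "nearest_peak_distance": dists}, index=gene_ids
    )


def intersect_with_targets(report: GeneClassificationReport) -> dict[str, int]:
    """Sizes of the ligand-regulated target set, the peak-associated sets,
    and all their pairwise/triple intersections."""
    targets = report.gene_set("ligand_regulated")
    mdm = report.gene_set("peak_associated_mdm")
    tam = report.gene_set("peak_associated_tam")
    return {
        "ligand_regulated": len(targets),
        "peak_associated_mdm": len(mdm),
        "peak_associated_tam": len(tam),
        "ligand_regulated&peak_associated_mdm": len(targets & mdm),
        "ligand_regulated&peak_associated_tam": len(targets & tam),
        "peak_associated_mdm&peak_associated_tam": len(mdm & tam),
        "ligand_regulated&peak_associated_mdm&peak_associated_tam": len(targets & mdm & tam),
        "ligand_regulated&peak_any": len(targets & (mdm | tam)),
    }
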