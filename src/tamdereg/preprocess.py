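"""Quantile normalization, expression filtering, FPKM from counts."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionStudy

__all__ = ["FilterResult", "quantile_normalize", "filter_expressed", "counts_to_fpkm"]


@dataclass(frozen=True)
class FilterResult:
    kept_gene_ids: list[str]
    dropped_gene_ids: list[str]
    thresholds: tuple[float, int]

    @property
    def kept(self) -> list[str]:
        return self.kept_gene_ids


def quantile_normalize(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes x samples matrix.

    Every output column carries the same sorted values: the across-sample
    mean of order statistics.  Tied values within a column receive the mean
    of the reference values at their tied ranks, which makes the result
    independent of input row order.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = fpkm.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = reference.copy()
        # average the reference over runs of equal column values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        for grp in np.split(np.arange(len(col)), boundaries):
            if len(grp) > 1:
                assigned[grp] = reference[grp].mean()
        out[order, j] = assigned
    return pd.DataFrame(out, index=fpkm.index, columns=fpkm.columns)


def filter_expressed(
    study: ExpressionStudy, min_fpkm: float = 0.3, min_tags: int = 50
) -> FilterResult:
    """Keep genes with FPKM >= min_fpkm AND tags >= min_tags jointly in at
    least one sample (both thresholds inclusive)."""
    if min_fpkm < 0 or min_tags < 0:
        raise ValueError("thresholds must be non-negative")
    ok = ((study.fpkm >= min_fpkm) & (study.tags >= min_tags)).any(axis=1)
    kept = list(study.fpkm.index[ok])
    dropped = list(study.fpkm.index[~ok])
    return FilterResult(kept_gene_ids=kept, dropped_gene_ids=dropped, thresholds=(min_fpkm, min_tags))


def counts_to_fpkm(tags: pd.DataFrame, gene_lengths_bp, libsizes) -> pd.DataFrame:
    """FPKM[g, s] = tags[g, s] * 1e9 / (length[g] * libsize[s])."""
    lengths = np.asarray(pd.Series(gene_lengths_bp).reindex(tags.index) if isinstance(gene_lengths_bp, (pd.Series, dict)) else gene_lengths_bp, dtype=float)
    libs = np.asarray(pd.Series(libsizes).reindex(tags.columns) if isinstance(libsizes, (pd.Series, dict)) else libsizes, dtype=float)
    if lengths.shape != (tags.shape[0],):
        raise ValueError("gene_lengths_bp must give one length per gene")
    if libs.shape != (tags.shape[1],):
        raise ValueError("libsizes must give one size per sample")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    vals = tags.to_numpy(dtype=float) * 1e9 / np.outer(lengths, libs)
    return pd.DataFrame(vals, index=tags.index, columns=tags.columns)
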