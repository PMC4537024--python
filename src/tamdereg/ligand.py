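"""Per-donor pairwise log fold changes and ligand-regulation classification.

The classification is threshold-based, mirroring how direct nuclear-receptor
target genes are called from paired treated/control RNA-Seq of the same
donor: a gene is ligand-regulated if it is agonist-induced, repressed by an
inverse agonist, or up in agonist versus inverse agonist, with a
consistency rule across donors (logFC >= 0.7 in 4 of 5 donor pairs by
default, generalized to ceil(0.8 * n)).
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CellType, ExpressionStudy, SampleMeta, Treatment

__all__ = [
    "Contrast",
    "ResponseTable",
    "pairwise_logfc",
    "consistent_regulation",
    "classify_mdm_targets",
    "classify_tam_response",
]

logger = logging.getLogger(__name__)

INVERSE_TREATMENTS = (Treatment.INVERSE_ST247, Treatment.INVERSE_PTS264)


class Contrast(str, enum.Enum):
    AGONIST_VS_DMSO = "AGONIST_vs_DMSO"
    INVERSE_VS_DMSO = "INVERSE_vs_DMSO"
    AGONIST_VS_INVERSE = "AGONIST_vs_INVERSE"


@dataclass
class ResponseTable:
    """Pairwise per-donor log2 fold changes for one contrast.

    ``logfc`` is genes x donors; ``median_logfc`` the per-gene median.
    """

    logfc: pd.DataFrame
    contrast: Contrast
    cell_type: CellType

    @property
    def median_logfc(self) -> pd.Series:
        return self.logfc.median(axis=1)

    @property
    def n_donors(self) -> int:
        return self.logfc.shape[1]


def _contrast_treatments(
    contrast: Contrast, inverse_treatment: Treatment
) -> tuple[Treatment, Treatment]:
    if contrast is Contrast.AGONIST_VS_DMSO:
        return Treatment.AGONIST, Treatment.DMSO
    if contrast is Contrast.INVERSE_VS_DMSO:
        return inverse_treatment, Treatment.DMSO
    return Treatment.AGONIST, inverse_treatment


def _pair_by_donor(
    study: ExpressionStudy,
    cell_type: CellType,
    treated: Treatment,
    control: Treatment,
) -> dict[str, tuple[str, str]]:
    """donor_id -> (treated sample_id, control sample_id); donors lacking
    either side are skipped with a warning."""
    by_donor: dict[str, dict[Treatment, list[SampleMeta]]] = {}
    for s in study.select(cell_type=cell_type):
        by_donor.setdefault(s.donor_id, {}).setdefault(s.treatment, []).append(s)
    pairs: dict[str, tuple[str, str]] = {}
    for donor, groups in sorted(by_donor.items()):
        t = groups.get(treated, [])
        c = groups.get(control, [])
        if len(t) == 1 and len(c) == 1:
            pairs[donor] = (t[0].sample_id, c[0].sample_id)
        elif t or c:
            logger.warning(
                "donor %s skipped for %s vs %s: %d treated / %d control samples",
                donor, treated.value, control.value, len(t), len(c),
            )
    return pairs


def pairwise_logfc(
    study: ExpressionStudy,
    contrast: Contrast,
    cell_type: CellType,
    pseudocount: float = 0.1,
    inverse_treatment: Treatment = Treatment.INVERSE_ST247,
) -> ResponseTable:
    """log2((FPKM_treated + pc) / (FPKM_control + pc)) per donor pair."""
    contrast = Contrast(contrast)
    cell_type = CellType(cell_type)
    treated, control = _contrast_treatments(contrast, inverse_treatment)
    pairs = _pair_by_donor(study, cell_type, treated, control)
    if not pairs:
        raise ValueError(
            f"no usable donor pairs for {contrast.value} in {cell_type.value}"
        )
    cols = {}
    for donor, (tid, cid) in pairs.items():
        cols[donor] = np.log2(
            (study.fpkm[tid] + pseudocount) / (study.fpkm[cid] + pseudocount)
        )
    return ResponseTable(logfc=pd.DataFrame(cols), contrast=contrast, cell_type=cell_type)


def consistent_regulation(
    pairwise: list[float],
    min_logfc: float = 0.7,
    min_fraction: float = 0.8,
    direction: str = "UP",
) -> bool:
    """True iff at least ceil(min_fraction * n) donor fold changes reach the
    threshold in the requested direction (>= min_logfc for UP, <= -min_logfc
    for DOWN).  With n = 5 and defaults this is the 4-of-5 rule."""
    values = np.asarray(list(pairwise), dtype=float)
    if values.size == 0:
        raise ValueError("empty fold-change list")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    needed = math.ceil(min_fraction * values.size)
    if direction == "UP":
        hits = int((values >= min_logfc).sum())
    elif direction == "DOWN":
        hits = int((values <= -min_logfc).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return hits >= needed


def _consistent_frame(
    logfc: pd.DataFrame, min_logfc: float, min_fraction: float, direction: str
) -> pd.Series:
    needed = math.ceil(min_fraction * logfc.shape[1])
    if direction == "UP":
        hits = (logfc >= min_logfc).sum(axis=1)
    else:
        hits = (logfc <= -min_logfc).sum(axis=1)
    return hits >= needed


def classify_mdm_targets(
    study: ExpressionStudy,
    min_logfc: float = 0.7,
    min_fraction: float = 0.8,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Three-way ligand-regulation flags for MDMs.

    Returns a DataFrame (index = gene_id) with nullable-boolean columns
    agonist_up_mdm, inverse_down_mdm, agonist_vs_inverse_up_mdm and
    ligand_regulated.  A comparison whose samples are missing leaves its
    flag absent (NA), not False.  The two inverse agonists are combined by
    union: regulation by either counts.
    """
    genes = study.fpkm.index
    na = pd.array([pd.NA] * len(genes), dtype="boolean")
    flags = pd.DataFrame(
        {
            "agonist_up_mdm": na,
            "inverse_down_mdm": na.copy(),
            "agonist_vs_inverse_up_mdm": na.copy(),
        },
        index=genes,
    )
    try:
        rt = pairwise_logfc(study, Contrast.AGONIST_VS_DMSO, CellType.MDM, pseudocount)
        flags["agonist_up_mdm"] = _consistent_frame(rt.logfc, min_logfc, min_fraction, "UP")
    except ValueError:
        logger.warning("agonist vs DMSO comparison unavailable in MDMs")

    for col, contrast, direction in (
        ("inverse_down_mdm", Contrast.INVERSE_VS_DMSO, "DOWN"),
        ("agonist_vs_inverse_up_mdm", Contrast.AGONIST_VS_INVERSE, "UP"),
    ):
        acc = None
        for inv in INVERSE_TREATMENTS:
            try:
                rt = pairwise_logfc(
                    study, contrast, CellType.MDM, pseudocount, inverse_treatment=inv
                )
            except ValueError:
                continue
            hit = _consistent_frame(rt.logfc, min_logfc, min_fraction, direction)
            acc = hit if acc is None else (acc | hit)
        if acc is not None:
            flags[col] = acc
        else:
            logger.warning("%s comparison unavailable in MDMs", contrast.value)

    union = (
        flags["agonist_up_mdm"].fillna(False)
        | flags["inverse_down_mdm"].fillna(False)
        | flags["agonist_vs_inverse_up_mdm"].fillna(False)
    )
    flags["ligand_regulated"] = union.astype("boolean")
    return flags


def classify_tam_response(
    study: ExpressionStudy,
    min_logfc: float = 1.0,
    min_fpkm: float = 0.3,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Agonist/inverse-agonist response of cultured TAMs.

    A gene is agonist-induced in TAMs iff the median per-donor pairwise
    logFC is >= min_logfc (inclusive) and the gene reaches min_fpkm in at
    least one of the TAM samples involved.  The linear fold change
    2**median_logfc is recorded for the downstream refractory comparison.
    """
    try:
        rt = pairwise_logfc(study, Contrast.AGONIST_VS_DMSO, CellType.TAM, pseudocount)
    except ValueError as exc:
        raise ValueError("no cultured TAM agonist/DMSO sample pairs") from exc
    tam_ids = [
        s.sample_id
        for s in study.select(cell_type=CellType.TAM)
        if s.treatment in (Treatment.AGONIST, Treatment.DMSO)
    ]
    expressed = (study.fpkm[tam_ids] >= min_fpkm).any(axis=1)
    med = rt.median_logfc
    out = pd.DataFrame(index=study.fpkm.index)
    out["agonist_up_tam"] = ((med >= min_logfc) & expressed).astype("boolean")
    out["median_logfc_agonist_tam"] = med
    out["tam_agonist_fc"] = np.power(2.0, med)

    inv_med = None
    for inv in INVERSE_TREATMENTS:
        try:
            rt_inv = pairwise_logfc(
                study, Contrast.INVERSE_VS_DMSO, CellType.TAM, pseudocount,
                inverse_treatment=inv,
            )
        except ValueError:
            continue
        m = rt_inv.median_logfc
        inv_med = m if inv_med is None else np.minimum(inv_med, m)
    if inv_med is not None:
        out["inverse_down_tam"] = ((inv_med <= -min_logfc) & expressed).astype("boolean")
    else:
        out["inverse_down_tam"] = pd.array([pd.NA] * len(out), dtype="boolean")
    return out
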