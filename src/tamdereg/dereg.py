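"""TAM-vs-MDM deregulation calls, t-test/FDR filtering, refractory genes.

Freshly isolated (ex vivo) TAM expression is compared against MDM solvent
controls by median FPKM ratio with an equal-variance t-test and
Benjamini-Hochberg FDR; agonist-inducible genes whose induction collapses
in TAMs (below the logFC threshold, or under half the MDM fold induction)
are called refractory.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    CellType,
    ExpressionStudy,
    GeneClassificationReport,
    Treatment,
)

__all__ = [
    "welchless_ttest",
    "bh_fdr",
    "call_up_in_tam_vivo",
    "call_up_in_tam_vitro",
    "call_refractory",
    "build_table1",
    "venn_summaries",
    "load_table1",
    "summarize_table1",
]

logger = logging.getLogger(__name__)

LOG_PSEUDOCOUNT = 0.1


def welchless_ttest(x, y) -> float:
    """Two-sided pooled-variance (equal-variance Student) t-test p-value.

    Degenerate zero-pooled-variance inputs follow the convention p = 1 for
    equal means and p = 0 for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 1.0
        logger.warning("zero pooled variance with unequal means; returning p=0")
        return 0.0
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _vivo_sample_ids(study: ExpressionStudy) -> tuple[list[str], list[str]]:
    tam = [s.sample_id for s in study.select(cell_type=CellType.TAM, treatment=Treatment.ASCITES)]
    mdm = [s.sample_id for s in study.select(cell_type=CellType.MDM, treatment=Treatment.DMSO)]
    return tam, mdm


def call_up_in_tam_vivo(
    study: ExpressionStudy,
    target_genes: set[str],
    min_logfc: float = 1.0,
    max_fdr: float = 0.05,
    apply_fdr: bool = True,
) -> pd.DataFrame:
    """Up/down-in-TAM (ex vivo) calls within the ligand-regulated target set.

    For each target gene: logFC = log2((median TAM FPKM + 0.1) /
    (median MDM FPKM + 0.1)); significance from an equal-variance t-test on
    log2(FPKM + 0.1) with BH correction across the target set.  A gene is
    up iff logFC >= min_logfc and (when apply_fdr) q <= max_fdr; the
    down-regulated set is symmetric at -min_logfc.
    """
    if not target_genes:
        raise ValueError("target_genes is empty")
    tam_ids, mdm_ids = _vivo_sample_ids(study)
    if len(tam_ids) < 2 or len(mdm_ids) < 2:
        raise ValueError(
            f"need >=2 ex vivo TAM and >=2 MDM DMSO samples, found {len(tam_ids)}/{len(mdm_ids)}"
        )
    genes = [g for g in study.fpkm.index if g in target_genes]
    tam_fpkm = study.fpkm.loc[genes, tam_ids]
    mdm_fpkm = study.fpkm.loc[genes, mdm_ids]
    med_tam = tam_fpkm.median(axis=1)
    med_mdm = mdm_fpkm.median(axis=1)
    logfc = np.log2((med_tam + LOG_PSEUDOCOUNT) / (med_mdm + LOG_PSEUDOCOUNT))
    log_tam = np.log2(tam_fpkm + LOG_PSEUDOCOUNT)
    log_mdm = np.log2(mdm_fpkm + LOG_PSEUDOCOUNT)
    pvals = np.array(
        [welchless_ttest(log_tam.loc[g], log_mdm.loc[g]) for g in genes]
    )
    qvals = bh_fdr(pvals)
    significant = (qvals <= max_fdr) if apply_fdr else np.ones(len(genes), dtype=bool)
    out = pd.DataFrame(
        {
            "median_fpkm_tam": med_tam,
            "median_fpkm_mdm": med_mdm,
            "logfc_vivo": logfc,
            "t_p": pvals,
            "fdr_q": qvals,
            "up_in_tam_vivo": (logfc >= min_logfc) & significant,
            "down_in_tam_vivo": (logfc <= -min_logfc) & significant,
        },
        index=genes,
    )
    return out


def call_up_in_tam_vitro(
    study: ExpressionStudy,
    target_genes: set[str],
    min_logfc: float = 0.7,
    min_fpkm_margin: float = 0.5,
    tam_sample_id: str | None = None,
    mdm_sample_ids: list[str] | None = None,
) -> pd.Series:
    """Up-in-cultured-TAM call: the TAM DMSO sample must exceed EVERY MDM
    DMSO sample both by min_logfc (log2 of the raw FPKM ratio) and by an
    absolute FPKM margin of min_fpkm_margin units."""
    if not target_genes:
        raise ValueError("target_genes is empty")
    if tam_sample_id is None:
        cands = [
            s.sample_id
            for s in study.select(cell_type=CellType.TAM, treatment=Treatment.DMSO)
        ]
        if not cands:
            raise ValueError("no cultured TAM DMSO sample in metadata")
        tam_sample_id = cands[0]
        if len(cands) > 1:
            logger.info("multiple cultured TAM DMSO samples; using %s", tam_sample_id)
    if mdm_sample_ids is None:
        mdm_sample_ids = [
            s.sample_id
            for s in study.select(cell_type=CellType.MDM, treatment=Treatment.DMSO)
        ]
    if len(mdm_sample_ids) < 2:
        raise ValueError("need >=2 MDM DMSO samples for the in vitro comparison")
    genes = [g for g in study.fpkm.index if g in target_genes]
    tam = study.fpkm.loc[genes, tam_sample_id]
    flag = pd.Series(True, index=genes)
    for mid in mdm_sample_ids:
        mdm = study.fpkm.loc[genes, mid]
        # raw ratio: the absolute-FPKM margin already guards the low end
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(tam / mdm)
        flag &= (lfc >= min_logfc) & (tam >= mdm + min_fpkm_margin)
    flag.name = "up_in_tam_vitro"
    return flag


def call_refractory(
    mdm_fc: float, tam_fc: float, tam_logfc: float, min_logfc: float = 1.0
) -> bool:
    """Refractory iff the TAM median logFC misses the TAM induction
    threshold, or the TAM fold induction is under half the MDM fold
    induction.  Caller must restrict to agonist-inducible-in-MDM genes."""
    if mdm_fc <= 0 or tam_fc <= 0:
        raise ValueError("fold changes must be positive")
    return bool(tam_logfc < min_logfc or tam_fc < 0.5 * mdm_fc)


def build_table1(
    report: GeneClassificationReport,
    dereg: pd.DataFrame,
    mdm_fc: pd.Series | None = None,
    symbols: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Summary table of ligand-regulated target genes upregulated in TAMs.

    Rows are genes with ligand_regulated AND up_in_tam_vivo; the peak
    column is '+' when a peak is associated in MDMs OR TAMs; refractory is
    '+'/'-' from the report flag.  Returns (table, counts).
    """
    rows = sorted(report.gene_set("ligand_regulated") & report.gene_set("up_in_tam_vivo"))
    peak_any = report.gene_set("peak_associated_mdm") | report.gene_set("peak_associated_tam")
    refractory = report.gene_set("refractory_in_tam")
    table = pd.DataFrame(
        {
            "gene": [symbols.get(g, g) if symbols is not None else g for g in rows],
            "agonist_mdm_fc": [
                float(mdm_fc.get(g, np.nan)) if mdm_fc is not None else np.nan
                for g in rows
            ],
            "peak": ["+" if g in peak_any else "-" for g in rows],
            "refractory": ["+" if g in refractory else "-" for g in rows],
        },
        index=pd.Index(rows, name="gene_id"),
    )
    counts = {
        "n_upregulated": len(rows),
        "n_refractory": int((table["refractory"] == "+").sum()),
        "n_peak": int((table["peak"] == "+").sum()),
    }
    return table, counts


def venn_summaries(report: GeneClassificationReport) -> dict[str, int]:
    """Overlap counts between the TAM-deregulation sets."""
    vivo = report.gene_set("up_in_tam_vivo")
    vitro = report.gene_set("up_in_tam_vitro")
    refr = report.gene_set("refractory_in_tam")
    ago = report.gene_set("agonist_up_mdm")
    inv = report.gene_set("inverse_down_mdm")
    avi = report.gene_set("agonist_vs_inverse_up_mdm")
    return {
        "up_in_tam_vivo": len(vivo),
        "up_in_tam_vitro": len(vitro),
        "up_in_tam_vivo&up_in_tam_vitro": len(vivo & vitro),
        "refractory_in_tam": len(refr),
        "up_in_tam_vivo&refractory_in_tam": len(vivo & refr),
        "agonist_up_mdm": len(ago),
        "inverse_down_mdm": len(inv),
        "agonist_vs_inverse_up_mdm": len(avi),
        "agonist_up_mdm&inverse_down_mdm": len(ago & inv),
        "agonist_up_mdm&agonist_vs_inverse_up_mdm": len(ago & avi),
        "inverse_down_mdm&agonist_vs_inverse_up_mdm": len(inv & avi),
    }


def load_table1() -> pd.DataFrame:
    """The packaged published gene table of TAM-upregulated target genes
    (gene symbol, description, agonist fold change in MDMs, peak and
    refractory annotations)."""
    from importlib.resources import files

    path = files("tamdereg").joinpath("data/tam_upregulated_targets.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"gene": str, "description": str})


def summarize_table1(table: pd.DataFrame) -> dict[str, int]:
    """Row count plus '+' counts of the peak and refractory columns."""
    return {
        "n_upregulated": int(len(table)),
        "n_refractory": int((table["refractory"].astype(str).str.strip() == "+").sum()),
        "n_peak": int((table["peak"].astype(str).str.strip() == "+").sum()),
    }
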