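"""End-to-end orchestration: expression filter -> ligand classification ->
peak assignment -> TAM deregulation and refractory calls -> report."""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import cistrome, dereg, ligand, preprocess
from .types import ExpressionStudy, GeneAnnotation, GeneClassificationReport, Peak

__all__ = ["run_classification"]


def run_classification(
    study: ExpressionStudy,
    annotation: list[GeneAnnotation] | None = None,
    tam_peaks_by_sample: dict[str, list[Peak]] | None = None,
    mdm_peaks_by_sample: dict[str, list[Peak]] | None = None,
    min_fpkm: float = 0.3,
    min_tags: int = 50,
    mdm_min_logfc: float = 0.7,
    mdm_min_fraction: float = 0.8,
    tam_min_logfc: float = 1.0,
    vivo_min_logfc: float = 1.0,
    max_fdr: float = 0.05,
    apply_fdr: bool = True,
    vitro_min_logfc: float = 0.7,
    vitro_min_fpkm_margin: float = 0.5,
    peak_min_tags: int = 30,
    peak_min_fc: float = 2.0,
    peak_min_samples: int = 2,
    peak_window_bp: int = 50_000,
    pseudocount: float = 0.1,
) -> GeneClassificationReport:
    """Run the full target-gene classification and return the report.

    Stages that lack their inputs (no peaks, no cultured TAM samples)
    leave the corresponding flags absent rather than False.
    """
    filt = preprocess.filter_expressed(study, min_fpkm=min_fpkm, min_tags=min_tags)
    genes = study.fpkm.index
    table = pd.DataFrame(index=genes)
    table["expressed"] = genes.isin(filt.kept_gene_ids)

    expressed_study = ExpressionStudy(
        fpkm=study.fpkm.loc[filt.kept_gene_ids],
        tags=study.tags.loc[filt.kept_gene_ids],
        samples=study.samples,
    )

    mdm_flags = ligand.classify_mdm_targets(
        expressed_study,
        min_logfc=mdm_min_logfc,
        min_fraction=mdm_min_fraction,
        pseudocount=pseudocount,
    )
    for col in mdm_flags.columns:
        full = pd.array([pd.NA] * len(genes), dtype="boolean")
        table[col] = full
        table.loc[mdm_flags.index, col] = mdm_flags[col]
        # genes dropped by the expression filter are definitively not called
        table.loc[~table["expressed"], col] = False

    target_genes = set(mdm_flags.index[mdm_flags["ligand_regulated"].fillna(False)])

    # peak association
    for label, peaks_by_sample in (
        ("peak_associated_tam", tam_peaks_by_sample),
        ("peak_associated_mdm", mdm_peaks_by_sample),
    ):
        if peaks_by_sample is None or annotation is None:
            table[label] = pd.array([pd.NA] * len(genes), dtype="boolean")
            continue
        filtered = {
            sid: cistrome.filter_peaks(ps, min_tags=peak_min_tags, min_fc=peak_min_fc)
            for sid, ps in peaks_by_sample.items()
        }
        consensus = cistrome.reproducible_peaks(filtered, min_samples=peak_min_samples)
        assigned = cistrome.assign_genes(consensus, annotation, window_bp=peak_window_bp)
        table[label] = pd.array([pd.NA] * len(genes), dtype="boolean")
        common = assigned.index.intersection(genes)
        table.loc[common, label] = assigned.loc[common, "peak_associated"].astype(bool)

    # TAM deregulation (ex vivo)
    table["up_in_tam_vivo"] = pd.array([pd.NA] * len(genes), dtype="boolean")
    table["fdr_q"] = np.nan
    table["median_logfc_tam_vs_mdm"] = np.nan
    if target_genes:
        try:
            vivo = dereg.call_up_in_tam_vivo(
                expressed_study,
                target_genes,
                min_logfc=vivo_min_logfc,
                max_fdr=max_fdr,
                apply_fdr=apply_fdr,
            )
        except ValueError:
            vivo = None
        if vivo is not None:
            table.loc[vivo.index, "up_in_tam_vivo"] = vivo["up_in_tam_vivo"]
            table.loc[vivo.index, "fdr_q"] = vivo["fdr_q"]
            table.loc[vivo.index, "median_logfc_tam_vs_mdm"] = vivo["logfc_vivo"]

    # cultured-TAM comparison
    table["up_in_tam_vitro"] = pd.array([pd.NA] * len(genes), dtype="boolean")
    if target_genes:
        try:
            vitro = dereg.call_up_in_tam_vitro(
                expressed_study,
                target_genes,
                min_logfc=vitro_min_logfc,
                min_fpkm_margin=vitro_min_fpkm_margin,
            )
            table.loc[vitro.index, "up_in_tam_vitro"] = vitro
        except ValueError:
            pass

    # refractory: agonist-inducible MDM genes whose TAM induction collapses
    table["refractory_in_tam"] = pd.array([pd.NA] * len(genes), dtype="boolean")
    try:
        tam_resp = ligand.classify_tam_response(
            expressed_study, min_logfc=tam_min_logfc, min_fpkm=min_fpkm,
            pseudocount=pseudocount,
        )
    except ValueError:
        tam_resp = None
    if tam_resp is not None:
        ago_up = mdm_flags.index[mdm_flags["agonist_up_mdm"].fillna(False)]
        mdm_agonist = ligand.pairwise_logfc(
            expressed_study, ligand.Contrast.AGONIST_VS_DMSO, "MDM", pseudocount
        )
        mdm_fc = np.power(2.0, mdm_agonist.median_logfc)
        refr = pd.Series(False, index=mdm_flags.index, dtype=bool)
        for g in ago_up:
            refr[g] = dereg.call_refractory(
                mdm_fc=float(mdm_fc[g]),
                tam_fc=float(tam_resp.loc[g, "tam_agonist_fc"]),
                tam_logfc=float(tam_resp.loc[g, "median_logfc_agonist_tam"]),
                min_logfc=tam_min_logfc,
            )
        table.loc[refr.index, "refractory_in_tam"] = refr
        table.loc[~table["expressed"], "refractory_in_tam"] = False

    return GeneClassificationReport(table=table)
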