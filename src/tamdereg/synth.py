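"""Ground-truth generators for every pipeline stage.

The generator emulates the study design the classification pipeline
assumes: five MDM donors with paired solvent/agonist/inverse-agonist
samples, ten freshly isolated (ex vivo) TAM patient samples, three
cultured-TAM donors with paired solvent/agonist samples, reproducible
ChIP peaks within 50 kb of planted direct targets plus sample-unique
decoys, and censored survival cohorts with an expression-dependent hazard.

Planted structure (all per-gene truth recorded in :class:`TruthLabels`
form): a set of direct targets is agonist-induced in MDMs (log2 induction
drawn around ``induction_logfc_mean``) and inverse-agonist-repressed at
half that magnitude; a nested subset is additionally upregulated at
baseline in TAMs; a further nested subset is refractory, with TAM agonist
induction attenuated to ``refractory_attenuation`` of the MDM fold change.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import counts_to_fpkm
from .types import (
    CellType,
    ExpressionStudy,
    GeneAnnotation,
    Medium,
    Peak,
    SampleMeta,
    Treatment,
)

__all__ = [
    "SimulationDesign",
    "simulate_expression",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_survival",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the synthetic study; defaults mirror the published
    set sizes (195 direct targets, 54 TAM-upregulated, 32 refractory,
    95 peak-associated) and cohort sizes (5 MDM donors, 10 TAM patients,
    3 cultured-TAM donors, 3 ChIP samples)."""

    n_genes: int = 2000
    n_direct_targets: int = 195
    frac_tam_up: float = 54 / 195
    frac_refractory_of_up: float = 32 / 54
    frac_peak_of_targets: float = 95 / 195
    mdm_donors: int = 5
    tam_patients: int = 10
    tam_cultured_donors: int = 3
    chip_samples: int = 3
    induction_logfc_mean: float = 3.0
    induction_logfc_sd: float = 0.5
    tam_baseline_logfc: float = 2.0
    refractory_attenuation: float = 0.2
    nb_dispersion: float = 0.01
    noise_sd_log2: float = 0.3
    donor_sd_log2: float = 0.2
    baseline_log2fpkm_mean: float = 3.0
    baseline_log2fpkm_sd: float = 2.0
    gene_length_range_bp: tuple[int, int] = (1000, 5000)
    libsize_range: tuple[int, int] = (20_000_000, 40_000_000)
    gene_spacing_bp: int = 300_000
    n_chromosomes: int = 5
    peak_window_bp: int = 50_000
    peak_width_bp: int = 400
    decoy_peaks: int = 300
    peak_tag_mean: float = 80.0
    igg_tag_mean: float = 5.0
    chip_libsize: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_tam_up", "frac_refractory_of_up", "frac_peak_of_targets"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_direct_targets > self.n_genes:
            raise ValueError("more direct targets than genes")
        if not 0 < self.refractory_attenuation < 1:
            raise ValueError("refractory_attenuation must be in (0, 1)")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mean + dispersion * mean^2;
    dispersion -> 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _truth_frame(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    targets = rng.choice(design.n_genes, size=design.n_direct_targets, replace=False)
    is_target = np.zeros(design.n_genes, dtype=bool)
    is_target[targets] = True
    n_up = int(round(design.frac_tam_up * design.n_direct_targets))
    up_idx = rng.choice(targets, size=n_up, replace=False)
    is_up = np.zeros(design.n_genes, dtype=bool)
    is_up[up_idx] = True
    n_refr = int(round(design.frac_refractory_of_up * n_up))
    refr_idx = rng.choice(up_idx, size=n_refr, replace=False)
    is_refr = np.zeros(design.n_genes, dtype=bool)
    is_refr[refr_idx] = True
    n_peak = int(round(design.frac_peak_of_targets * design.n_direct_targets))
    peak_idx = rng.choice(targets, size=n_peak, replace=False)
    has_peak = np.zeros(design.n_genes, dtype=bool)
    has_peak[peak_idx] = True
    induction = np.zeros(design.n_genes)
    induction[is_target] = rng.normal(
        design.induction_logfc_mean, design.induction_logfc_sd, size=design.n_direct_targets
    )
    tam_induction = induction.copy()
    tam_induction[is_refr] = induction[is_refr] + np.log2(design.refractory_attenuation)
    return pd.DataFrame(
        {
            "is_direct_target": is_target,
            "is_tam_up": is_up,
            "is_refractory": is_refr,
            "has_peak": has_peak,
            "planted_mdm_logfc": induction,
            "planted_tam_logfc": tam_induction,
            "planted_mdm_fc": np.power(2.0, induction) * is_target,
            "planted_tam_fc": np.power(2.0, tam_induction) * is_target,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def simulate_expression(
    design: SimulationDesign,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Generate an expression study plus per-gene truth labels.

    The FPKM matrix is log-normal around a per-gene baseline with a
    per-donor random effect and per-sample noise; tag counts are
    negative-binomial around the exact FPKM-implied mean, and the returned
    FPKM matrix is recomputed from the counts via :func:`counts_to_fpkm`
    so the two matrices are mutually consistent by construction.
    """
    rng = np.random.default_rng(design.seed)
    truth = _truth_frame(design, rng)
    n = design.n_genes
    baseline = rng.normal(
        design.baseline_log2fpkm_mean, design.baseline_log2fpkm_sd, size=n
    )
    lengths = rng.integers(*design.gene_length_range_bp, size=n, endpoint=True)

    samples: list[SampleMeta] = []
    effects: list[np.ndarray] = []  # per-sample log2 offsets (condition + donor)

    def donor_effect() -> float:
        return rng.normal(0.0, design.donor_sd_log2)

    tam_up_shift = np.where(truth["is_tam_up"], design.tam_baseline_logfc, 0.0)

    for d in range(design.mdm_donors):
        donor = f"MDMd{d+1}"
        de = donor_effect()
        for treatment, shift in (
            (Treatment.DMSO, np.zeros(n)),
            (Treatment.AGONIST, truth["planted_mdm_logfc"].to_numpy()),
            (Treatment.INVERSE_ST247, -0.5 * truth["planted_mdm_logfc"].to_numpy()),
            (Treatment.INVERSE_PTS264, -0.5 * truth["planted_mdm_logfc"].to_numpy()),
        ):
            sid = f"{donor}_{treatment.value}"
            samples.append(
                SampleMeta(sid, CellType.MDM, donor, treatment, Medium.R10, donor)
            )
            effects.append(de + shift)

    for p in range(design.tam_patients):
        donor = f"TAMp{p+1}"
        sid = f"{donor}_exvivo"
        samples.append(
            SampleMeta(sid, CellType.TAM, donor, Treatment.ASCITES, Medium.ASCITES, donor)
        )
        effects.append(donor_effect() + tam_up_shift)

    for d in range(design.tam_cultured_donors):
        donor = f"TAMc{d+1}"
        de = donor_effect()
        for treatment, shift in (
            (Treatment.DMSO, tam_up_shift),
            (Treatment.AGONIST, tam_up_shift + truth["planted_tam_logfc"].to_numpy()),
        ):
            sid = f"{donor}_{treatment.value}"
            samples.append(
                SampleMeta(sid, CellType.TAM, donor, treatment, Medium.ASCITES, donor)
            )
            effects.append(de + shift)

    n_samples = len(samples)
    libsizes = rng.integers(*design.libsize_range, size=n_samples, endpoint=True)
    log2fpkm = (
        baseline[:, None]
        + np.column_stack(effects)
        + rng.normal(0.0, design.noise_sd_log2, size=(n, n_samples))
    )
    true_fpkm = np.power(2.0, log2fpkm)
    mean_tags = true_fpkm * lengths[:, None] * libsizes[None, :] / 1e9
    tags_mat = _nb_draw(rng, mean_tags, design.nb_dispersion)

    sample_ids = [s.sample_id for s in samples]
    gene_index = truth.index
    tags = pd.DataFrame(tags_mat, index=gene_index, columns=sample_ids, dtype=np.int64)
    fpkm = counts_to_fpkm(
        tags,
        pd.Series(lengths, index=gene_index),
        pd.Series(libsizes, index=sample_ids),
    )
    study = ExpressionStudy(fpkm=fpkm, tags=tags, samples=samples)
    truth = truth.copy()
    truth["gene_length_bp"] = lengths
    return study, truth


def simulate_annotation(design: SimulationDesign) -> list[GeneAnnotation]:
    """Deterministic TSS layout: genes spaced ``gene_spacing_bp`` apart on
    ``n_chromosomes`` chromosomes, so neighboring 50-kb windows never
    overlap and decoys can be placed in the gaps."""
    records = []
    per_chrom = -(-design.n_genes // design.n_chromosomes)
    for i in range(design.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        pos_on_chrom = i % per_chrom
        tss = design.gene_spacing_bp // 2 + pos_on_chrom * design.gene_spacing_bp
        records.append(
            GeneAnnotation(
                gene_id=f"G{i:05d}",
                symbol=f"SYN{i:05d}",
                chrom=chrom,
                strand="+" if i % 2 == 0 else "-",
                tss=tss,
            )
        )
    return records


def simulate_peaks(
    design: SimulationDesign,
    truth: pd.DataFrame,
    annotation: list[GeneAnnotation],
    seed: int | None = None,
) -> dict[str, list[Peak]]:
    """ChIP peak calls for ``chip_samples`` TAM samples.

    Every has_peak gene receives a ``peak_width_bp`` peak placed uniformly
    within +/- peak_window_bp of its TSS (clipped so the peak edge stays
    inside the window), present in at least two of the samples; decoy
    peaks are sample-unique and placed farther than peak_window_bp from
    every TSS, so the two-of-n reproducibility rule removes them.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    ann = {a.gene_id: a for a in annotation}
    missing = [g for g in truth.index[truth["has_peak"]] if g not in ann]
    if missing:
        raise ValueError(f"annotation missing has_peak genes: {missing[:5]}")
    sample_ids = [f"TAMchip{i+1}" for i in range(design.chip_samples)]
    peaks: dict[str, list[Peak]] = {sid: [] for sid in sample_ids}
    half_w = design.peak_window_bp
    width = design.peak_width_bp

    for gene_id in truth.index[truth["has_peak"]]:
        a = ann[gene_id]
        lo = max(0, a.tss - half_w)
        hi = a.tss + half_w - width
        start = int(rng.integers(lo, max(lo + 1, hi)))
        end = start + width
        if rng.random() < 0.7:
            chosen = sample_ids
        else:
            chosen = list(rng.choice(sample_ids, size=2, replace=False))
        for sid in chosen:
            # jitter per sample so member intervals overlap but differ
            jitter = int(rng.integers(-width // 4, width // 4 + 1))
            s = max(lo, start + jitter)
            peaks[sid].append(
                Peak(
                    chrom=a.chrom,
                    start=s,
                    end=s + width,
                    sample_id=sid,
                    tags=int(_nb_draw(rng, np.array(design.peak_tag_mean), design.nb_dispersion)),
                    igg_tags=int(_nb_draw(rng, np.array(design.igg_tag_mean), design.nb_dispersion)),
                    sample_libsize=design.chip_libsize,
                    igg_libsize=design.chip_libsize,
                )
            )

    # decoys: one sample each, in the inter-gene gap, > 50 kb from every TSS;
    # one decoy per distinct gene slot so decoys never overlap each other
    spacing = design.gene_spacing_bp
    n_decoys = min(design.decoy_peaks, len(truth))
    decoy_slots = rng.choice(len(truth), size=n_decoys, replace=False)
    margin = half_w + 10_000
    for slot in decoy_slots:
        a = ann[truth.index[int(slot)]]
        start = int(rng.integers(a.tss + margin, a.tss + spacing - margin - width))
        sid = sample_ids[int(rng.integers(0, len(sample_ids)))]
        peaks[sid].append(
            Peak(
                chrom=a.chrom,
                start=start,
                end=start + width,
                sample_id=sid,
                tags=int(_nb_draw(rng, np.array(design.peak_tag_mean), design.nb_dispersion)),
                igg_tags=int(_nb_draw(rng, np.array(design.igg_tag_mean), design.nb_dispersion)),
                sample_libsize=design.chip_libsize,
                igg_libsize=design.chip_libsize,
            )
        )
    return peaks


def simulate_survival(
    n: int,
    hr: float,
    cutoff_frac: float = 0.5,
    censor_rate: float = 0.02,
    seed: int = 0,
    baseline_hazard: float = np.log(2) / 18.0,
) -> pd.DataFrame:
    """Cohort with exponential event times (months); the top ``cutoff_frac``
    of a standard-normal expression marker has its hazard multiplied by
    ``hr``.  Censoring is independent exponential at ``censor_rate``
    (0 disables censoring).
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 < cutoff_frac < 1:
        raise ValueError("cutoff_frac must be in (0, 1)")
    if baseline_hazard <= 0 or censor_rate < 0:
        raise ValueError("degenerate rates")
    rng = np.random.default_rng(seed)
    expression = rng.normal(size=n)
    threshold = np.quantile(expression, 1.0 - cutoff_frac)
    high = expression > threshold
    hazard = baseline_hazard * np.where(high, hr, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    return pd.DataFrame(
        {"time": time, "event": event, "expression": expression, "high_risk": high}
    )
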