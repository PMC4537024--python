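import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tamdereg.synth import SimulationDesign, simulate_annotation, simulate_expression, simulate_peaks
from tamdereg.types import CellType, ExpressionStudy, Medium, SampleMeta, Treatment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("tamdereg").setLevel(logging.ERROR)


def make_study(fpkm: dict, tags: dict | None = None, samples: list[SampleMeta] | None = None):
    """Small hand-built study; fpkm/tags map sample_id -> list of values."""
    fpkm_df = pd.DataFrame(fpkm)
    fpkm_df.index = [f"G{i}" for i in range(len(fpkm_df))]
    if tags is None:
        tags_df = pd.DataFrame(
            np.full(fpkm_df.shape, 1000, dtype=np.int64),
            index=fpkm_df.index,
            columns=fpkm_df.columns,
        )
    else:
        tags_df = pd.DataFrame(tags, index=fpkm_df.index, dtype=np.int64)
    if samples is None:
        samples = [
            SampleMeta(sid, CellType.MDM, f"D{i}", Treatment.DMSO, Medium.R10, f"D{i}")
            for i, sid in enumerate(fpkm_df.columns)
        ]
    return ExpressionStudy(fpkm=fpkm_df, tags=tags_df, samples=samples)


def mdm_pair_study(treated_fpkm, control_fpkm, pseudo_tags=1000):
    """Per-donor MDM agonist/DMSO pairs: treated_fpkm/control_fpkm are
    genes x donors arrays."""
    treated_fpkm = np.atleast_2d(np.asarray(treated_fpkm, dtype=float))
    control_fpkm = np.atleast_2d(np.asarray(control_fpkm, dtype=float))
    n_genes, n_donors = treated_fpkm.shape
    data, samples = {}, []
    for d in range(n_donors):
        donor = f"D{d}"
        for treatment, col in (
            (Treatment.AGONIST, treated_fpkm[:, d]),
            (Treatment.DMSO, control_fpkm[:, d]),
        ):
            sid = f"{donor}_{treatment.value}"
            data[sid] = col
            samples.append(SampleMeta(sid, CellType.MDM, donor, treatment, Medium.R10, donor))
    fpkm = pd.DataFrame(data, index=[f"G{i}" for i in range(n_genes)])
    tags = pd.DataFrame(
        np.full(fpkm.shape, pseudo_tags, dtype=np.int64), index=fpkm.index, columns=fpkm.columns
    )
    return ExpressionStudy(fpkm=fpkm, tags=tags, samples=samples)


@pytest.fixture(scope="session")
def default_sim():
    """One default-design synthetic dataset shared across tests."""
    design = SimulationDesign(seed=7)
    study, truth = simulate_expression(design)
    annotation = simulate_annotation(design)
    peaks = simulate_peaks(design, truth, annotation)
    return design, study, truth, annotation, peaks
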