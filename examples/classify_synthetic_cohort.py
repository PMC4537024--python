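"""Simulate a full study (expression + ChIP peaks) with planted truth and
run the end-to-end target-gene classification.

Prints the main set sizes and the recovery of the planted classes.  The
default design plants 195 ligand-regulated direct targets, 54 of them
upregulated in TAMs and 32 of those refractory to the synthetic agonist,
with reproducible ChIP peaks at 95 targets.
"""
import logging

from tamdereg.pipeline import run_classification
from tamdereg.synth import SimulationDesign, simulate_annotation, simulate_expression, simulate_peaks

logging.disable(logging.WARNING)

design = SimulationDesign(seed=1)
study, truth = simulate_expression(design)
annotation = simulate_annotation(design)
peaks = simulate_peaks(design, truth, annotation)

report = run_classification(study, annotation=annotation, tam_peaks_by_sample=peaks)
counts = report.summary_counts()

print(f"genes simulated:            {design.n_genes}")
print(f"expressed (FPKM/tag filter): {counts['expressed']}")
print(f"ligand-regulated targets:   {counts['ligand_regulated']}")
print(f"  with TAM ChIP peak:       {counts['ligand_regulated&peak_associated_tam']}")
print(f"up in TAM (ex vivo):        {counts['up_in_tam_vivo']}")
print(f"  also refractory:          {counts['up_in_tam_vivo&refractory_in_tam']}")
print(f"up in cultured TAM:         {counts['up_in_tam_vitro']}")

pred = report.gene_set("ligand_regulated")
true = set(truth.index[truth.is_direct_target])
tp = len(pred & true)
print(f"recovery of planted targets: precision {tp/len(pred):.3f}, recall {tp/len(true):.3f}")
print("A precise, near-complete recovery means the threshold rules reassemble")
print("the planted regulatory structure from the noisy matrices alone.")
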