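"""Summarize an ascites fatty-acid panel: cohort median, mass-to-molar
conversion and comparison with the receptor-activation concentration."""
import numpy as np

from tamdereg.lipidomics import (
    PANEL,
    CohortConcentrations,
    fold_over_ic50,
    mass_to_molar,
    present_rounded,
)

rng = np.random.default_rng(0)
# synthetic cohort of 38 patients centered on a 50 ug/ml median
values = tuple(np.sort(rng.lognormal(np.log(50), 0.5, size=38)))
la = PANEL["linoleic acid"]
cohort = CohortConcentrations(la, values, "ug/ml")

median_um = mass_to_molar(cohort.median, "ug/ml", la)
print(f"linoleic acid: median {cohort.median:.1f} ug/ml "
      f"= {median_um:.1f} uM (~{present_rounded(median_um):.0f} uM)")
print(f"fold over the {la.ic50} uM receptor IC50: {fold_over_ic50(median_um, la):.0f}x")

pgf = PANEL["6-keto-PGF1alpha"]
nm = mass_to_molar(10.0, "ng/ml", pgf)
print(f"6-keto-PGF1alpha: 10 ng/ml = {nm:.1f} nM (~{present_rounded(nm):.0f} nM)")
print("A median orders of magnitude above the IC50 marks an analyte as a")
print("plausible endogenous receptor agonist; nanomolar ones are not.")
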