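"""Simulate a crossover fiber-intervention cohort with one planted species.

Builds a gene catalog organized into MSPs, draws a 2-arm 2-period crossover
cohort, plants a Cliff's-delta-0.7 increase on one species in the
multi-fiber arm, and checks the realized effect size.
"""

import fibrascope as fs
from fibrascope import design as dsg
from fibrascope.stats import cliffs_delta

catalog = fs.generate_catalog(n_genes=3000, n_msp=25, seed=1)
print(f"catalog: {catalog.n_genes} genes in {len(catalog.msp_ids)} MSPs "
      f"(+{(catalog.frame['msp_id'] == '').sum()} unassigned)")

effect = fs.PlantedEffect("msp_0007", cliffs_delta_target=0.7)
design, composition = fs.generate_cohort(catalog, n_subjects=39,
                                         effects=(effect,), seed=2)
n_mf_first = (design.drop_duplicates("subject_id")["sequence"]
              == dsg.SEQ_MF_FIRST).sum()
print(f"cohort: 39 subjects x 4 visits = {len(design)} samples; "
      f"{n_mf_first} subjects start on multi-fiber bread")

pairs = dsg.paired_samples(design, dsg.MULTI_FIBER)
cd = cliffs_delta(composition.loc[pairs["post"], "msp_0007"],
                  composition.loc[pairs["pre"], "msp_0007"])
print(f"realized Cliff's delta of msp_0007 (post vs pre, MF arm): {cd:.2f}")
print("-> the planted multiplicative shift lands near its 0.7 target; the")
print("   remaining gap is finite-sample noise plus simplex renormalization.")
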