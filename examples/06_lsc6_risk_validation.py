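"""LSC6 risk binning and immune-signature enrichment vs risk.

Builds a bulk cohort in which stemness (LSC6) genes and exhausted-T-cell
genes both scale with blast fraction, scores LSC6 with user-supplied
coefficients (the published weights are not bundled), bins samples into
low/medium/high risk, and correlates immune ssGSEA scores with risk.
"""

import numpy as np
import pandas as pd

from blastsig.riskval import LSC6_GENES, Lsc6Model, enrichment_vs_risk, lsc6_score, risk_bin
from blastsig.scoring import EXHAUSTED_T, M1_MACROPHAGE, GeneSetLibrary
from blastsig.syndata import BulkCohort

rng = np.random.default_rng(17)
n = 150
b = rng.uniform(0.1, 1.0, size=n)  # latent blast/stemness burden
cols = list(LSC6_GENES) + EXHAUSTED_T + M1_MACROPHAGE + [f"F{j}" for j in range(300)]
expr = pd.DataFrame(rng.lognormal(2, 1.0, size=(n, len(cols))), columns=cols,
                    index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
for g in list(LSC6_GENES) + EXHAUSTED_T:
    expr[g] *= 1 + 3 * b          # exhaustion tracks stemness burden
for g in M1_MACROPHAGE:
    expr[g] *= 1 + 3 * (1 - b)    # inflammatory macrophages track its absence
cohort = BulkCohort(expression=expr,
                    meta=pd.DataFrame({"blast_pct": 100 * b, "timepoint": "Dx"},
                                      index=expr.index))

# example coefficients for demonstration; substitute the published weights
coefs = {"DNMT3B": 0.08, "GPR56": 0.05, "CD34": 0.02, "SOCS2": 0.06,
         "SPINK2": 0.10, "FAM30A": 0.03}
lsc6 = lsc6_score(cohort, Lsc6Model(coefficients=coefs))
bins = risk_bin(lsc6)
print("risk bins:", bins.value_counts().to_dict())

sets = GeneSetLibrary({"exhaustedT": EXHAUSTED_T, "M1": M1_MACROPHAGE})
corr, pairwise = enrichment_vs_risk(cohort, sets, lsc6)
for name, row in corr.iterrows():
    print(f"{name:10s} vs LSC6: Pearson r={row['pearson_r']:+.3f} "
          f"(p={row['p']:.2e})")
print(pairwise.to_string(index=False))
# Exhausted T cells enrich with higher leukemic-stem-cell risk (r > 0) while
# inflammatory M1 macrophages deplete (r < 0) - the expected immune pattern
# of high-risk marrow.
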