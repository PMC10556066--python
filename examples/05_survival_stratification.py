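"""Stratify a simulated cohort by signature enrichment and test survival.

Survival times are generated with hazard increasing in the enrichment score
(beta = 1 per SD); the cohort is split at the median and at the optimal
log-rank cutpoint, and both splits are tested.
"""

import numpy as np

from blastsig import survstats
from blastsig.syndata import SimConfig, generate_survival

cfg = SimConfig(survival_beta=1.0, censor_rate=0.2, seed=17)
score = np.random.default_rng(17).normal(size=200)
surv = generate_survival(score, cfg)
t, e = surv["os_time"].to_numpy(), surv["os_event"].to_numpy()

for rule in ("median", "cutp"):
    res = survstats.survival_by_score(score, t, e, rule=rule)
    extra = ""
    if rule == "cutp":
        extra = (f", corrected p={res.cutp_p_corrected:.4f}"
                 f" (uncorrected {res.cutp_p_uncorrected:.2e})")
    print(f"{rule:6s}: cut={res.cutpoint:+.3f}  n_high={res.n_high} "
          f"n_low={res.n_low}  HR={res.hr:.2f} "
          f"[{res.hr_ci[0]:.2f}, {res.hr_ci[1]:.2f}]  "
          f"log-rank p={res.logrank_p:.2e}{extra}")

fit = survstats.cox_univariate((score - score.mean()) / score.std(), t, e)
print(f"continuous Cox: beta={fit['coef']:.3f} (simulated 1.0), "
      f"HR/SD={fit['hr']:.2f}, p={fit['p']:.2e}")
# High-enrichment patients die earlier: HR > 1 under either split, and the
# continuous Cox coefficient recovers the simulated log-hazard per SD. The
# cutpoint scan reports a selection-corrected p because it tries many cuts.
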