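"""Run the full signature-discovery funnel on a simulated study.

Single-cell DE -> bulk blast-percentage filter -> off-target filter ->
SVM-RFE, printing the gene list surviving each stage and the cross-validated
AUC by panel size.
"""

from blastsig.sigdiscovery import DiscoveryConfig, discover_signature
from blastsig.syndata import (
    SimConfig, expression_profiles, generate_bulk_cohort, generate_single_cell,
)

cfg = SimConfig(seed=17)
adata = generate_single_cell(cfg)
prof = expression_profiles(cfg)
cohort = generate_bulk_cohort(cfg, prof["blast"], prof["normal"])

trace = discover_signature(adata, cohort, DiscoveryConfig(seed=17))

print(f"stage 1 (single-cell DEGs, FC>1.2 adjP<0.01): {len(trace.stage1_sc_de)} genes")
print(f"stage 2 (bulk progressive filter, FC>1.8):    {len(trace.stage2_bulk)} genes "
      f"-> {trace.stage2_bulk}")
print(f"stage 3 (off-target filter):                  {len(trace.stage3_offtarget)} genes")
for size, auc in sorted(trace.cv_auc_by_size.items()):
    print(f"  panel size {size}: mean out-of-fold AUC = {auc:.4f}")
print(f"final panel ({len(trace.final_panel)} genes): {trace.final_panel}")
planted = set(cfg.planted_genes)
print(f"planted markers recovered: {len(planted & set(trace.final_panel))}/7")
# Stage 1 carries ~100+ patient-heterogeneity false positives; the bulk and
# off-target filters remove them, and the SVM picks the smallest panel whose
# AUC is within 0.005 of the best - the minimal blast signature.
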