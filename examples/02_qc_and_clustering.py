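"""Demultiplex, QC-filter and cluster a cohort in two passes.

Pass one corrects well batch and donor so nuclei group by cell type; pass
two re-clusters the endothelial subset correcting only the well batch, so
disease structure is retained and the disease-enriched capillary state
separates from the healthy one.
"""

import pandas as pd

from incitekit import pipeline, synthetic

cohort = synthetic.generate_cohort(synthetic.CohortConfig(seed=1))
res = pipeline.run_default_analysis(cohort, seed=0, gsea_n_perm=200)

print("QC report (counts of nuclei failing each rule):")
for k, v in res.qc_report.items():
    print(f"  {k}: {v}")

print("\nfirst-pass clusters vs ground-truth cell types:")
print(pd.crosstab(res.meta["true_celltype"], res.first_pass.labels))

print("\nendothelial subclusters: fraction of disease-group nuclei")
print(res.subcluster_disease_fraction.round(3))
print(
    f"disease-enriched subcluster: {res.disease_cluster}; "
    f"control-enriched: {res.control_cluster}"
)
# A disease fraction near 1.0 in one subcluster and ~0.3 in the others
# reproduces the disease-specific capillary state: nearly all its nuclei
# come from AD/ALS/FTD donors.
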