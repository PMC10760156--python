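"""The NF-kB -> TDP-43 stoichiometry analysis and the decoupling statistic.

Plots-as-numbers: binned means of TDP-43 against NF-kB per donor group
(both on the ln(target/H3) scale), then the decoupling statistic — the mean
departure of TDP-43 from the pooled-control prediction in the top-25%
NF-kB stratum, with hierarchical-bootstrap confidence intervals and
ANOVA/Tukey comparisons across groups.
"""

import pandas as pd

from incitekit import protein, stoichiometry, synthetic

cohort = synthetic.generate_cohort(
    synthetic.stoichiometry_cohort_config(
        decoupling_delta=-0.5, seed=1, n_donors_per_group=4, nuclei_per_donor=250
    )
)
lh = protein.quantify(cohort.adt).log_h3
meta = cohort.meta.loc[lh.index]

curve = stoichiometry.stoich_curve(
    lh["NFkB"], lh["TDP43"], meta["disease_state"], n_bins=10
)
print("binned TDP-43 means in the top NF-kB bins (decoupling is visible only there):")
top = curve[curve["bin"] >= 8].pivot(index="bin", columns="group", values="mean")
print(top.round(3))

res = stoichiometry.decoupling_statistic(
    lh["NFkB"], lh["TDP43"], meta["disease_state"], meta["donor_id"],
    n_boot=300, seed=0,
)
summary = pd.concat([res.delta, res.ci, res.n_top], axis=1)
print("\ndecoupling delta-hat per group (injected: -0.5 in AD/ALS/FTD):")
print(summary.round(3))
print(f"\nANOVA across groups in the top stratum: F={res.anova_F:.1f}, "
      f"p={res.anova_p:.2e}")
print("Tukey HSD vs controls:")
print(res.tukey.round(4))
# Disease-group deltas near the injected -0.5 with CIs excluding 0, and
# control deltas with CIs covering 0, show the statistic recovers the
# engineered breakdown of the TDP-43/NF-kB relationship.
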