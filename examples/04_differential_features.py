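"""Discriminative features between heterogeneity groups and pathway mapping.

Builds patient-level feature means, compares low- vs high-heterogeneity
patients with a fold-change/Welch-t volcano, correlates features with
subpopulation presence, and runs hypergeometric pathway over-representation
against a toy annotation catalog.
"""

import numpy as np
import pandas as pd

from msihet import (
    SyntheticConfig,
    diversity_table,
    generate_cohort,
    kmeans_segment,
    optimal_cutoff,
    pathway_enrichment,
    patient_feature_means,
    presence_matrix,
    rms_normalize,
    subpop_correlation,
    volcano,
)
from msihet.dataio import FeatureCatalog

cfg = SyntheticConfig(n_patients=40, pixels_per_core=80, n_features=40, seed=19)
pixels, clinical, _, _ = generate_cohort(cfg)
norm = rms_normalize(pixels)
seg = kmeans_segment(norm, cfg.n_clusters_true, seed=0, n_init=4)
pres = presence_matrix(seg, norm)

div = diversity_table(pres, norm)
cut = optimal_cutoff(div, clinical)
means = patient_feature_means(norm)

vol = volcano(means, cut.group_labels, fc_threshold=1.5, alpha=0.05)
n_up = int((vol["passes"] & (vol["direction"] == "up_high")).sum())
n_dn = int((vol["passes"] & (vol["direction"] == "up_low")).sum())
print(f"discriminative features: {n_up} up in high-, {n_dn} up in low-heterogeneity")

corr = subpop_correlation(means, pres)
sig = corr[corr["p"] < 0.05]
print(f"significant feature–subpopulation correlations: {len(sig)} of {len(corr)}")

# toy annotation: first 10 features in PW_A, next 10 in PW_B
catalog = FeatureCatalog(
    pd.DataFrame(
        {
            "feature_index": np.arange(1, 41),
            "mz": np.linspace(60, 950, 40),
            "metabolite_name": [f"met{i}" for i in range(1, 41)],
            "pathway_ids": [frozenset({"PW_A"}) if i <= 10 else
                            frozenset({"PW_B"}) if i <= 20 else frozenset()
                            for i in range(1, 41)],
            "drug_pathway_ids": [frozenset() for _ in range(40)],
        }
    )
)
enr = pathway_enrichment(corr, catalog)
print("\nmost over-represented (cluster, direction, pathway) rows:")
print(enr.nsmallest(4, "p").round(4))
# p is the hypergeometric upper tail of the pathway's overlap with the
# significantly correlated feature set; unadjusted, as everywhere here
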