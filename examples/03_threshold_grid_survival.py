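"""Optimize the cluster-presence threshold by Cox AIC and fit survival models.

Sweeps presence thresholds (2–50 %), scores each presence-indicator Cox model
by AIC, selects the admissible minimum, assigns patients to subpopulations at
the chosen threshold (a patient may carry several), and fits the
counting-process (Andersen–Gill) and multivariate models.
"""

import numpy as np

from msihet import (
    SyntheticConfig,
    andersen_gill_fit,
    assign_patients,
    default_tau_grid,
    generate_cohort,
    grid_search,
    kmeans_segment,
    multivariate_cox,
    presence_matrix,
    rms_normalize,
    select_model,
)

cfg = SyntheticConfig(
    n_patients=100, pixels_per_core=80, n_features=60,
    log_hazard_effects={1: 1.5}, presence_threshold_true=0.20, seed=3,
)
pixels, clinical, _, truth = generate_cohort(cfg)
norm = rms_normalize(pixels)

presences = {}
for k in (4, 5, 6):
    seg = kmeans_segment(norm, k, seed=0, n_init=4)
    presences[k] = presence_matrix(seg, norm)

grid = grid_search(presences, clinical, default_tau_grid())
print(grid.best_per_k()[["k", "threshold", "aic", "global_p"]].round(4))
# lowest-AIC admissible threshold per k (the white squares of a grid heatmap)

sel = select_model(grid)
print(f"\nselected (k*, tau*) = {sel.selected}  [planted tau = 0.20]")

asg = assign_patients(presences[sel.selected[0]], sel.selected[1], clinical)
print(f"memberships: {len(asg.members)} (patients may join several subpopulations)")

ag = andersen_gill_fit(asg, clinical)
print("\nAndersen–Gill contrasts vs the reference subpopulation (robust SE):")
print(ag.summary.round(3))

mv = multivariate_cox(asg, clinical)
print("\nmultivariate model (subpopulations + stage + age + sex):")
print(mv.summary.round(3))
subs = mv.summary[mv.summary.index.str.startswith("sub_")]
best = subs["coef"].idxmax()
print(
    f"\n{best} carries the largest subpopulation log-HR "
    f"({subs.loc[best, 'coef']:.2f}, Wald p = {subs.loc[best, 'wald_p']:.3g}): "
    "the planted prognostic subpopulation is flagged as an independent risk factor"
)
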