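"""Pooled two-cohort segmentation and shared/specific subpopulation calls.

Pixels from two cohorts (e.g. normal adrenal cortex and tumor) are
RMS-normalized and clustered together in one k-means run, so the resulting
subpopulations are defined on a common spectral scale.  A subpopulation is
"present" in a cohort when at least ``min_patients`` of that cohort's
patients carry it above the presence fraction ``tau_presence``; it is then
classified shared or cohort-specific.  The presence rule is a configurable
convention (defaults: 1 patient at 5 %), since "presented in" has no unique
numeric definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataio import PixelTable, rms_normalize
from .segmentation import PresenceMatrix, SegmentationResult, kmeans_segment, presence_matrix

__all__ = ["CohortComparison", "pooled_segment_and_compare"]


@dataclass
class CohortComparison:
    """Per-cluster cohort composition and shared/specific classification.

    ``table`` columns: cluster, the two cohorts' shares of the cluster's
    pixels (summing to 1 per cluster), patient counts above the presence
    rule, and ``class`` in {shared, <A>_specific, <B>_specific, absent}.
    """

    cohort_a: str
    cohort_b: str
    table: pd.DataFrame
    segmentation: SegmentationResult
    presence_a: PresenceMatrix
    presence_b: PresenceMatrix
    tau_presence: float
    min_patients: int


def pooled_segment_and_compare(
    table_a: PixelTable,
    table_b: PixelTable,
    k: int,
    tau_presence: float = 0.05,
    min_patients: int = 1,
    seed: int = 0,
    n_init: int = 10,
    normalize: bool = True,
) -> CohortComparison:
    """Cluster two cohorts in one run and classify each subpopulation.

    The two tables must share one feature catalog (same channels); cohort
    names are taken from their ``cohort`` columns and must be single-valued
    and distinct.  Patient ids must not collide across cohorts.
    """
    name_a = _cohort_name(table_a)
    name_b = _cohort_name(table_b)
    if name_a == name_b:
        raise ValueError("the two tables carry the same cohort label")
    if table_a.feature_cols != table_b.feature_cols:
        raise ValueError("cohorts must share one feature catalog")
    overlap = set(table_a.patients()) & set(table_b.patients())
    if overlap:
        raise ValueError(f"patient ids appear in both cohorts: {sorted(overlap)[:5]}")
    pooled = PixelTable(
        pd.concat([table_a.frame, table_b.frame], ignore_index=True)
    )
    if normalize:
        pooled = rms_normalize(pooled)
    seg = kmeans_segment(pooled, k, seed=seed, n_init=n_init)

    in_a = pooled.frame["cohort"] == name_a
    sub_a = pooled.subset(in_a)
    sub_b = pooled.subset(~in_a)
    pres_a = presence_matrix(seg, sub_a)
    pres_b = presence_matrix(seg, sub_b)

    lab = seg.labels
    counts_a = (
        lab.loc[sub_a.pixel_ids.to_numpy()].value_counts().reindex(range(1, k + 1), fill_value=0)
    )
    counts_b = (
        lab.loc[sub_b.pixel_ids.to_numpy()].value_counts().reindex(range(1, k + 1), fill_value=0)
    )
    rows = []
    for c in range(1, k + 1):
        tot = counts_a[c] + counts_b[c]
        above_a = int((pres_a.frame[c] >= tau_presence).sum())
        above_b = int((pres_b.frame[c] >= tau_presence).sum())
        present_a = above_a >= min_patients
        present_b = above_b >= min_patients
        if present_a and present_b:
            cls = "shared"
        elif present_a:
            cls = f"{name_a}_specific"
        elif present_b:
            cls = f"{name_b}_specific"
        else:
            cls = "absent"
        rows.append(
            {
                "cluster": c,
                f"pixel_share_{name_a}": counts_a[c] / tot if tot else 0.0,
                f"pixel_share_{name_b}": counts_b[c] / tot if tot else 0.0,
                f"patients_above_{name_a}": above_a,
                f"patients_above_{name_b}": above_b,
                "class": cls,
            }
        )
    return CohortComparison(
        cohort_a=name_a,
        cohort_b=name_b,
        table=pd.DataFrame(rows),
        segmentation=seg,
        presence_a=pres_a,
        presence_b=pres_b,
        tau_presence=tau_presence,
        min_patients=min_patients,
    )


def _cohort_name(table: PixelTable) -> str:
    names = table.frame["cohort"].unique()
    if len(names) != 1:
        raise ValueError(f"table must hold exactly one cohort, found {list(names)}")
    return str(names[0])
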