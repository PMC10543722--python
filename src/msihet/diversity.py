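"""Per-patient metabolic heterogeneity via Simpson's diversity index.

The Gini-Simpson index ``D = 1 - sum_i p_i^2`` is the probability that two
pixels drawn at random (with replacement) from one patient's tumor fall in
different metabolic subpopulations.  ``D = 0`` means all pixels share one
subpopulation; the maximum for k subpopulations is ``1 - 1/k``.  The module
also links the index to ordinal tumor stage (Spearman correlation, pairwise
Mann-Whitney U) and splits the cohort into low/high heterogeneity groups at
the cutoff minimizing the two-sided log-rank p-value.

All p-values are reported unadjusted.  Because the survival cutoff is
data-driven, its minimal p-value is optimistically biased; results carry an
explicit ``optimism_warning`` flag rather than a correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from .dataio import ClinicalTable, PixelTable
from .segmentation import PresenceMatrix, SegmentationResult

__all__ = [
    "simpson_index",
    "diversity_table",
    "stage_association",
    "optimal_cutoff",
    "DiversityTable",
    "StageAssociation",
    "CutoffResult",
]


def simpson_index(counts, finite_sample: bool = False) -> float:
    """Gini-Simpson diversity of a per-cluster pixel-count vector.

    Parameters
    ----------
    counts
        Non-negative integers, one per cluster; their sum is the patient's
        pixel count and must be positive.
    finite_sample
        If True, use the without-replacement (unbiased) form
        ``1 - sum c_i (c_i - 1) / (N (N - 1))``; the default is the
        with-replacement form ``1 - sum (c_i / N)^2``.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or (c < 0).any():
        raise ValueError("counts must be a 1-D non-negative vector")
    n = c.sum()
    if n <= 0:
        raise ValueError("counts sum to zero: no pixels")
    if finite_sample:
        if n < 2:
            raise ValueError("finite-sample form needs at least 2 pixels")
        return float(1.0 - (c * (c - 1.0)).sum() / (n * (n - 1.0)))
    p = c / n
    return float(1.0 - (p**2).sum())


@dataclass
class DiversityTable:
    """Per-patient Simpson index with pixel and cluster counts."""

    frame: pd.DataFrame  # patient_id, simpson, n_pixels, n_clusters_present

    def series(self) -> pd.Series:
        return self.frame.set_index("patient_id")["simpson"]


def diversity_table(
    presence: PresenceMatrix,
    table: PixelTable,
    seg: SegmentationResult | None = None,
    finite_sample: bool = False,
) -> DiversityTable:
    """Simpson index per patient from that patient's pixel counts.

    Counts are reconstructed from the presence fractions and the patient's
    total pixel count, so the result matches a direct per-pixel tally.
    """
    totals = table.frame.groupby("patient_id").size()
    rows = []
    for pid, frac in presence.frame.iterrows():
        n = int(totals.loc[pid])
        counts = np.rint(frac.to_numpy() * n)
        rows.append(
            {
                "patient_id": pid,
                "simpson": simpson_index(counts, finite_sample=finite_sample),
                "n_pixels": n,
                "n_clusters_present": int((counts > 0).sum()),
            }
        )
    return DiversityTable(pd.DataFrame(rows))


@dataclass
class StageAssociation:
    """Spearman link of diversity to ordinal stage plus pairwise U tests."""

    rho: float
    p: float
    pairwise: pd.DataFrame  # stage_a, stage_b, n_a, n_b, u, p
    notes: list


def stage_association(div: DiversityTable, clinical: ClinicalTable) -> StageAssociation:
    """Correlate per-patient diversity with tumor stage.

    Spearman's rho treats stage as ranked; stage pairs are additionally
    compared with unpaired two-sided Mann-Whitney U tests.  P-values are
    unadjusted.  Stage pairs with an empty side are skipped with a note.
    """
    merged = div.frame.merge(clinical.frame, on="patient_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 patients")
    if merged["stage"].nunique() < 2:
        raise ValueError("need at least 2 stages represented")
    rho, p = stats.spearmanr(merged["stage"], merged["simpson"])
    notes = []
    rows = []
    stages = sorted(merged["stage"].unique())
    for i, sa in enumerate(stages):
        for sb in stages[i + 1 :]:
            a = merged.loc[merged["stage"] == sa, "simpson"]
            b = merged.loc[merged["stage"] == sb, "simpson"]
            if len(a) == 0 or len(b) == 0:
                notes.append(f"stage pair ({sa},{sb}) skipped: empty group")
                continue
            u, up = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {"stage_a": sa, "stage_b": sb, "n_a": len(a), "n_b": len(b), "u": u, "p": up}
            )
    for s in range(1, 5):
        if s not in stages:
            notes.append(f"stage {s} has 0 patients; pairs involving it skipped")
    return StageAssociation(rho=float(rho), p=float(p), pairwise=pd.DataFrame(rows), notes=notes)


@dataclass
class CutoffResult:
    """Low/high heterogeneity split at the minimal-log-rank-p cutoff."""

    cutoff: float
    group_labels: pd.Series  # patient_id -> 'low' | 'high'
    logrank_p: float
    group_sizes: tuple
    candidates: pd.DataFrame  # cutoff, p, n_low, n_high
    optimism_warning: str = (
        "cutoff chosen to minimize the log-rank p-value; the reported p is "
        "optimistically biased and unadjusted"
    )


def optimal_cutoff(
    div: DiversityTable,
    clinical: ClinicalTable,
    min_group_frac: float = 0.1,
) -> CutoffResult:
    """Split patients into low/high diversity at the minimal log-rank p.

    Candidate cutoffs are the midpoints between consecutive sorted unique
    index values; candidates leaving either group smaller than
    ``min_group_frac * n`` are excluded.  Ties on p are broken toward the
    more balanced split, then toward the smaller cutoff.
    """
    if not 0 < min_group_frac < 0.5:
        raise ValueError("min_group_frac must lie in (0, 0.5)")
    merged = div.frame.merge(clinical.frame, on="patient_id")
    vals = np.sort(merged["simpson"].unique())
    if len(vals) < 2:
        raise ValueError("need at least 2 distinct diversity values")
    n = len(merged)
    min_size = min_group_frac * n
    rows = []
    for cut in (vals[:-1] + vals[1:]) / 2.0:
        low = merged["simpson"] < cut
        n_low, n_high = int(low.sum()), int((~low).sum())
        if n_low < min_size or n_high < min_size:
            continue
        res = logrank_test(
            merged.loc[low, "time"],
            merged.loc[~low, "time"],
            event_observed_A=merged.loc[low, "event"],
            event_observed_B=merged.loc[~low, "event"],
        )
        rows.append({"cutoff": float(cut), "p": float(res.p_value), "n_low": n_low, "n_high": n_high})
    if not rows:
        raise ValueError("no admissible cutoff candidate under min_group_frac")
    cand = pd.DataFrame(rows)
    order = cand.assign(imbalance=(cand["n_low"] - cand["n_high"]).abs()).sort_values(
        ["p", "imbalance", "cutoff"], kind="stable"
    )
    bestrow = order.iloc[0]
    cut = float(bestrow["cutoff"])
    labels = pd.Series(
        np.where(merged["simpson"] < cut, "low", "high"),
        index=merged["patient_id"].to_numpy(),
        name="heterogeneity",
    )
    return CutoffResult(
        cutoff=cut,
        group_labels=labels,
        logrank_p=float(bestrow["p"]),
        group_sizes=(int(bestrow["n_low"]), int(bestrow["n_high"])),
        candidates=cand.reset_index(drop=True),
    )
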