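"""Discriminative features between heterogeneity groups and per-subpopulation
feature/pathway association.

The test unit throughout is the patient: pixel intensities are first averaged
per patient so that the thousands of pixels of one tumor do not masquerade as
independent replicates.  Group comparison (low vs high heterogeneity) uses
fold change of patient-level means plus a two-sided Welch t-test; a feature is
discriminative when |FC| >= 1.5-fold and p < 0.05.  Feature-to-subpopulation
association is the Pearson correlation of per-patient feature means with
per-patient presence fractions; significantly correlated features are mapped
onto user-supplied pathway and drug-action-pathway annotations by
hypergeometric over-representation.  All p-values are unadjusted
(``UNADJUSTED_NOTE``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .dataio import FeatureCatalog, PixelTable
from .segmentation import PresenceMatrix

__all__ = [
    "UNADJUSTED_NOTE",
    "patient_feature_means",
    "volcano",
    "heatmap_matrix",
    "subpop_correlation",
    "pathway_enrichment",
    "drug_pathway_association",
    "HeatmapResult",
]

UNADJUSTED_NOTE = "all p-values are unadjusted for multiple testing"


def patient_feature_means(table: PixelTable) -> pd.DataFrame:
    """Mean intensity per patient per feature over the patient's ROI pixels."""
    return table.frame.groupby("patient_id")[table.feature_cols].mean()


def volcano(
    means: pd.DataFrame,
    group_labels: pd.Series,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fold change and Welch t-test of every feature between two groups.

    ``group_labels`` maps patient -> 'low' | 'high'.  Fold change is
    mean(high) / mean(low) of the patient-level means; a feature passes when
    ``fc >= fc_threshold`` or ``fc <= 1/fc_threshold`` and ``p < alpha``.
    Features with a zero denominator mean are flagged (``fc_defined=False``)
    and never pass.  Swapping the two labels exactly negates ``log2_fc``.
    """
    groups = set(group_labels.unique())
    if groups != {"low", "high"}:
        raise ValueError(f"group labels must be 'low'/'high', got {groups}")
    hi = means.loc[group_labels[group_labels == "high"].index]
    lo = means.loc[group_labels[group_labels == "low"].index]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("both groups need at least 2 patients")
    m_hi = hi.mean(axis=0).to_numpy()
    m_lo = lo.mean(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m_hi / m_lo
        t, p = stats.ttest_ind(hi.to_numpy(), lo.to_numpy(), axis=0, equal_var=False)
    fc_defined = m_lo > 0
    out = pd.DataFrame(
        {
            "feature": means.columns,
            "feature_index": np.arange(1, means.shape[1] + 1),
            "mean_high": m_hi,
            "mean_low": m_lo,
            "fc": np.where(fc_defined, fc, np.nan),
            "log2_fc": np.where(fc_defined & (fc > 0), np.log2(np.where(fc > 0, fc, 1.0)), np.nan),
            "p": p,
            "fc_defined": fc_defined,
        }
    )
    big = (out["fc"] >= fc_threshold) | (out["fc"] <= 1.0 / fc_threshold)
    out["passes"] = out["fc_defined"] & big.fillna(False) & (out["p"] < alpha)
    out["direction"] = np.where(out["fc"] >= 1.0, "up_high", "up_low")
    out.loc[~out["fc_defined"], "direction"] = "undefined"
    return out


@dataclass
class HeatmapResult:
    """Autoscaled top-feature matrix with hierarchical row/column orders."""

    matrix: pd.DataFrame  # features × patients, autoscaled, reordered
    row_order: list
    col_order: list
    features: list = field(default_factory=list)


def heatmap_matrix(means: pd.DataFrame, volcano_df: pd.DataFrame, top_n: int = 50) -> HeatmapResult:
    """Top-``top_n`` features by ascending p, autoscaled and Ward-clustered.

    Rows (features) are scaled to zero mean and unit variance across
    patients; both axes are ordered by agglomerative hierarchical clustering
    (Ward linkage on Euclidean distance).  Purely presentational, but the
    orderings are deterministic and exported for reproducibility.
    """
    ranked = volcano_df.dropna(subset=["p"]).sort_values(["p", "feature"], kind="stable")
    feats = ranked["feature"].head(top_n).tolist()
    if len(feats) < 2:
        raise ValueError("need at least 2 ranked features")
    M = means[feats].T  # features × patients
    sd = M.std(axis=1, ddof=0).replace(0.0, 1.0)
    Z = M.sub(M.mean(axis=1), axis=0).div(sd, axis=0)
    row_order = leaves_list(linkage(Z.to_numpy(), method="ward")).tolist()
    col_order = leaves_list(linkage(Z.to_numpy().T, method="ward")).tolist()
    Zo = Z.iloc[row_order, col_order]
    return HeatmapResult(
        matrix=Zo,
        row_order=[feats[i] for i in row_order],
        col_order=[Z.columns[i] for i in col_order],
        features=feats,
    )


def subpop_correlation(means: pd.DataFrame, presence: PresenceMatrix) -> pd.DataFrame:
    """Pearson correlation of each feature mean with each presence fraction.

    Returns the long (feature, cluster) table with ``r``, the two-sided
    t-distribution p-value and ``n``; pairs where either side has zero
    variance are flagged (``defined=False``) rather than given a fabricated
    r.  Needs at least 3 common patients.
    """
    common = means.index.intersection(presence.frame.index)
    if len(common) < 3:
        raise ValueError("need at least 3 patients")
    X = means.loc[common].to_numpy(dtype=float)  # n × F
    P = presence.frame.loc[common].to_numpy(dtype=float)  # n × k
    n = len(common)
    Xc = X - X.mean(axis=0)
    Pc = P - P.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sp = np.sqrt((Pc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Pc) / np.outer(sx, sp)  # F × k
        R = np.clip(R, -1.0, 1.0)
        tstat = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    defined = np.outer(sx > 0, sp > 0)
    rows = []
    for fi, feat in enumerate(means.columns):
        for ci, cl in enumerate(presence.frame.columns):
            ok = bool(defined[fi, ci])
            rows.append(
                {
                    "feature": feat,
                    "feature_index": fi + 1,
                    "cluster": int(cl),
                    "r": R[fi, ci] if ok else np.nan,
                    "p": pval[fi, ci] if ok else np.nan,
                    "n": n,
                    "defined": ok,
                }
            )
    return pd.DataFrame(rows)


def _hypergeom_upper(n_hits: int, n_universe: int, n_pathway: int, n_selected: int) -> float:
    """P(X >= n_hits) for X ~ Hypergeom(universe, pathway, selected)."""
    return float(stats.hypergeom.sf(n_hits - 1, n_universe, n_pathway, n_selected))


def pathway_enrichment(
    corr: pd.DataFrame,
    catalog: FeatureCatalog,
    alpha: float = 0.05,
    kind: str = "pathway_ids",
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways per subpopulation.

    For each cluster and direction (sign of r among significantly correlated
    features), the selected set is tested against every pathway within the
    universe of annotated features.  Pathways with no annotated feature in
    the universe are skipped.  Returns rows (cluster, direction, pathway_id,
    n_hits, n_pathway, n_selected, n_universe, p).
    """
    sets = catalog.pathway_sets(kind)
    universe = sorted(fi for fi, s in sets.items() if s)
    n_universe = len(universe)
    if n_universe == 0:
        return pd.DataFrame(
            columns=["cluster", "direction", "pathway_id", "n_hits", "n_pathway",
                     "n_selected", "n_universe", "p"]
        )
    pathways: dict[str, set] = {}
    for fi in universe:
        for pw in sets[fi]:
            pathways.setdefault(pw, set()).add(fi)
    rows = []
    for cl in sorted(corr["cluster"].unique()):
        sub = corr[(corr["cluster"] == cl) & corr["defined"] & (corr["p"] < alpha)]
        for direction, sign in (("up", 1), ("down", -1)):
            selected = set(sub.loc[np.sign(sub["r"]) == sign, "feature_index"]) & set(universe)
            for pw, members in sorted(pathways.items()):
                hits = len(selected & members)
                rows.append(
                    {
                        "cluster": int(cl),
                        "direction": direction,
                        "pathway_id": pw,
                        "n_hits": hits,
                        "n_pathway": len(members),
                        "n_selected": len(selected),
                        "n_universe": n_universe,
                        "p": _hypergeom_upper(hits, n_universe, len(members), len(selected)),
                    }
                )
    return pd.DataFrame(rows)


def drug_pathway_association(
    corr: pd.DataFrame,
    catalog: FeatureCatalog,
    alpha: float = 0.05,
    min_metabolites: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subpopulation ↔ drug-action-pathway association via correlated metabolites.

    A (cluster, drug pathway) association exists when at least
    ``min_metabolites`` annotated features correlate significantly (p <
    alpha) with the cluster.  Returns ``(associations, edges)``: the edge
    list carries each contributing feature with the sign of its correlation
    (the positive/negative edges of the association network).
    """
    sets = catalog.pathway_sets("drug_pathway_ids")
    annotated = {fi: s for fi, s in sets.items() if s}
    edges = []
    sig = corr[corr["defined"] & (corr["p"] < alpha)]
    for _, row in sig.iterrows():
        for pw in annotated.get(int(row["feature_index"]), ()):
            edges.append(
                {
                    "cluster": int(row["cluster"]),
                    "drug_pathway_id": pw,
                    "feature": row["feature"],
                    "feature_index": int(row["feature_index"]),
                    "r": row["r"],
                    "sign": "positive" if row["r"] >= 0 else "negative",
                }
            )
    edges_df = pd.DataFrame(
        edges,
        columns=["cluster", "drug_pathway_id", "feature", "feature_index", "r", "sign"],
    )
    if edges_df.empty:
        assoc = pd.DataFrame(columns=["cluster", "drug_pathway_id", "n_metabolites"])
    else:
        assoc = (
            edges_df.groupby(["cluster", "drug_pathway_id"])
            .size()
            .rename("n_metabolites")
            .reset_index()
        )
        assoc = assoc[assoc["n_metabolites"] >= min_metabolites].reset_index(drop=True)
    return assoc, edges_df
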