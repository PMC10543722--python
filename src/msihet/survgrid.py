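"""Linking subpopulation presence to survival via Cox models on a (k, τ) grid.

For a segmentation with k subpopulations and a presence threshold τ, each
cluster yields a binary patient covariate 1[p_ic >= τ].  A single Cox
proportional-hazards model (Efron ties, partial likelihood) on all
non-constant indicators is scored by its AIC ``2 p − 2 ℓ``; sweeping τ over
a percent grid and k over the segmentation range produces the model-selection
heatmap.  A model is admissible when it is non-degenerate and its global
likelihood-ratio p-value is below 0.05; among admissible rows the minimal
AIC wins (ties toward smaller k, then smaller τ).  An empty admissible set
is reported as an explicit abstention, not an error.

A model is flagged degenerate when no indicator varies, when an indicator
coincides with the event status (it then completely determines who died),
when the likelihood is monotone (a diverging coefficient), or when the
fit fails to converge.

Patients at the selected (k*, τ*) are assigned to every subpopulation whose
presence fraction reaches τ*; because a patient may carry several
subpopulations, between-subpopulation survival contrasts use the
counting-process (Andersen-Gill style) layout — one row per
patient-membership with the patient's time and event repeated — fitted with
a patient-clustered robust sandwich variance and Wald tests.  P-values are
unadjusted throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats

from .dataio import ClinicalTable
from .segmentation import PresenceMatrix

__all__ = [
    "CoxFit",
    "GridResult",
    "ModelSelection",
    "MembershipAssignment",
    "null_partial_loglik",
    "cox_presence_aic",
    "grid_search",
    "select_model",
    "assign_patients",
    "andersen_gill_fit",
    "multivariate_cox",
    "pairwise_subpopulation_tests",
    "default_tau_grid",
]

#: |coef| above which a presence-indicator fit is treated as a monotone
#: likelihood (hazard ratio beyond ~e^8 on a binary covariate).
_MONOTONE_COEF = 8.0


def default_tau_grid(lo: float = 0.02, hi: float = 0.50, step: float = 0.01) -> np.ndarray:
    """Presence-threshold grid, by default 2 %..50 % in 1 % steps."""
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


@dataclass
class CoxFit:
    """A fitted proportional-hazards model in reporting shape.

    ``summary`` is indexed by term with columns ``coef`` (log hazard ratio),
    ``hr``, ``ci_low``, ``ci_high`` (95 %), ``se`` and ``wald_p``; ``se`` is
    robust when ``robust`` is set.
    """

    summary: pd.DataFrame
    loglik: float
    model_aic: float
    n_params: int
    ties_method: str = "efron"
    robust: bool = False
    cluster_variable: str | None = None
    variance_matrix: pd.DataFrame | None = field(default=None, repr=False)
    dropped: list = field(default_factory=list)


@dataclass
class GridResult:
    """All (k, τ) rows of the model grid."""

    frame: pd.DataFrame  # k, threshold, aic, loglik, n_params, global_p,
    #                      degenerate, n_assigned_clusters, note

    def best_per_k(self) -> pd.DataFrame:
        """Lowest-AIC admissible threshold for each k (heatmap annotation)."""
        ok = self.frame[~self.frame["degenerate"]]
        if ok.empty:
            return ok
        idx = ok.sort_values(["aic", "threshold"], kind="stable").groupby("k").head(1)
        return idx.sort_values("k").reset_index(drop=True)

    def matrix(self, value: str = "aic") -> pd.DataFrame:
        """k × τ matrix of ``value`` for heatmap rendering."""
        return self.frame.pivot(index="k", columns="threshold", values=value)


@dataclass
class ModelSelection:
    """Outcome of the grid selection; ``selected`` is None on abstention."""

    selected: tuple | None  # (k, tau)
    reason: str
    row: pd.Series | None = None

    @property
    def abstained(self) -> bool:
        return self.selected is None


def null_partial_loglik(time, event) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    With all risk scores equal, the Efron denominator for the l-th of d tied
    deaths at a time with n at risk is ``n − l``, so
    ``ℓ0 = −Σ_times Σ_{l<d} log(n − l)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        ll -= sum(np.log(n - l) for l in range(d))
    return float(ll)


def _lifelines_fit(df: pd.DataFrame, robust: bool = False, cluster_col: str | None = None):
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        cph.fit(
            df,
            duration_col="time",
            event_col="event",
            robust=robust,
            cluster_col=cluster_col,
        )
    return cph

def _coxfit_from(cph, robust: bool, cluster_col: str | None, dropped: list) -> CoxFit:
    summ = cph.summary
    with np.errstate(over="ignore"):
        out = pd.DataFrame(
            {
                "coef": summ["coef"],
                "hr": summ["exp(coef)"],
                "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
                "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
                "se": summ["se(coef)"],
                "wald_p": summ["p"],
            }
        )
    return CoxFit(
        summary=out,
        loglik=float(cph.log_likelihood_),
        model_aic=float(cph.AIC_partial_),
        n_params=len(out),
        robust=robust,
        cluster_variable=cluster_col,
        variance_matrix=cph.variance_matrix_,
        dropped=dropped,
    )


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Greedily drop constant or linearly dependent columns (later ones lose)."""
    keep: list = []
    notes: list = []
    for c in X.columns:
        col = X[c].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            notes.append(f"dropped constant column {c}")
            continue
        M = X[keep + [c]].to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        if np.linalg.matrix_rank(M) < len(keep) + 1:
            notes.append(f"dropped collinear column {c}")
            continue
        keep.append(c)
    return X[keep], notes


def cox_presence_aic(
    presence: PresenceMatrix, clinical: ClinicalTable, tau: float
) -> tuple[CoxFit | None, dict]:
    """Fit the presence-indicator Cox model at one threshold.

    Returns the fit (None when nothing could be fit) and a grid-row dict.
    The row's AIC uses the fitted partial likelihood; with no varying
    indicator the null model's ``−2 ℓ0`` is reported with 0 parameters.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    clin = clinical.frame.set_index("patient_id").loc[presence.frame.index]
    if int(clin["event"].sum()) == 0:
        raise ValueError("no events in the cohort")
    ind = presence.binarize(tau)
    ind.columns = [f"sub_{c}" for c in ind.columns]
    n_assigned = int((ind.sum(axis=0) > 0).sum())
    kept, notes = _drop_collinear(ind)  # constants and duplicates (k=2 gives
    varying = list(kept.columns)  #        complementary indicators) drop here
    constant = [c for c in ind.columns if c not in varying]
    row = {
        "threshold": float(tau),
        "n_assigned_clusters": n_assigned,
        "note": "",
    }
    if constant:
        row["note"] = f"indicators dropped (constant/collinear): {','.join(constant)}"
    if not varying:
        ll0 = null_partial_loglik(clin["time"], clin["event"])
        row.update(
            aic=-2.0 * ll0, loglik=ll0, n_params=0, global_p=1.0, degenerate=True,
            note=(row["note"] + "; " if row["note"] else "") + "no varying indicator",
        )
        return None, row

    ev = clin["event"].to_numpy()
    separating = [
        c
        for c in varying
        if np.array_equal(ind[c].to_numpy(), ev) or np.array_equal(ind[c].to_numpy(), 1 - ev)
    ]
    df = pd.concat([clin[["time", "event"]], ind[varying]], axis=1)
    try:
        cph = _lifelines_fit(df)
    except (ConvergenceError, ConvergenceWarning, Exception) as exc:  # flagged, not raised
        ll0 = null_partial_loglik(clin["time"], clin["event"])
        row.update(
            aic=np.nan, loglik=np.nan, n_params=len(varying), global_p=np.nan,
            degenerate=True,
            note=(row["note"] + "; " if row["note"] else "") + f"fit failed: {type(exc).__name__}",
        )
        return None, row
    fit = _coxfit_from(cph, robust=False, cluster_col=None, dropped=constant)
    monotone = fit.summary["coef"].abs().max() > _MONOTONE_COEF
    degenerate = bool(separating) or monotone
    if separating:
        row["note"] = (row["note"] + "; " if row["note"] else "") + (
            "indicator determines event status: " + ",".join(separating)
        )
    elif monotone:
        row["note"] = (row["note"] + "; " if row["note"] else "") + "monotone likelihood"
    lrt = cph.log_likelihood_ratio_test()
    row.update(
        aic=fit.model_aic,
        loglik=fit.loglik,
        n_params=fit.n_params,
        global_p=float(lrt.p_value),
        degenerate=degenerate,
    )
    return fit, row


def grid_search(
    presences: dict[int, PresenceMatrix],
    clinical: ClinicalTable,
    taus: np.ndarray | None = None,
) -> GridResult:
    """Evaluate the presence-indicator model over every (k, τ) pair."""
    if taus is None:
        taus = default_tau_grid()
    rows = []
    for k in sorted(presences):
        for tau in taus:
            _, row = cox_presence_aic(presences[k], clinical, float(tau))
            row["k"] = int(k)
            rows.append(row)
    frame = pd.DataFrame(rows)[
        [
            "k",
            "threshold",
            "aic",
            "loglik",
            "n_params",
            "global_p",
            "degenerate",
            "n_assigned_clusters",
            "note",
        ]
    ]
    return GridResult(frame=frame)


def select_model(grid: GridResult, alpha: float = 0.05) -> ModelSelection:
    """Pick the admissible (k*, τ*) row with minimal AIC, or abstain."""
    f = grid.frame
    if f.empty:
        raise ValueError("empty grid")
    ok = f[(~f["degenerate"]) & (f["global_p"] < alpha) & f["aic"].notna()]
    if ok.empty:
        return ModelSelection(selected=None, reason="no admissible model: every row degenerate or not significant")
    best = ok.sort_values(["aic", "k", "threshold"], kind="stable").iloc[0]
    return ModelSelection(
        selected=(int(best["k"]), float(best["threshold"])),
        reason="minimal AIC among non-degenerate rows with global p < %.3g" % alpha,
        row=best,
    )


@dataclass
class MembershipAssignment:
    """Patients assigned to every subpopulation reaching the threshold."""

    chosen_k: int
    chosen_threshold: float
    members: pd.DataFrame  # patient_id, cluster
    excluded_clusters: list
    long_format: pd.DataFrame  # patient_id, cluster, time, event

    def members_of(self, cluster: int) -> list:
        return self.members.loc[self.members["cluster"] == cluster, "patient_id"].tolist()

    def counts(self) -> pd.Series:
        return self.members.groupby("cluster").size()


def assign_patients(
    presence: PresenceMatrix, tau: float, clinical: ClinicalTable
) -> MembershipAssignment:
    """Threshold the presence matrix into (patient, subpopulation) members.

    A patient joins every cluster with ``p_ic >= tau`` (possibly several, or
    none); clusters without any member are listed in ``excluded_clusters``.
    ``long_format`` repeats the patient's time and event once per membership
    for counting-process fits.
    """
    ind = presence.binarize(tau)
    pairs = [
        (pid, int(c))
        for pid, row in ind.iterrows()
        for c in ind.columns[row.to_numpy().astype(bool)]
    ]
    members = pd.DataFrame(pairs, columns=["patient_id", "cluster"])
    excluded = [int(c) for c in ind.columns if c not in set(members["cluster"])]
    clin = clinical.frame.set_index("patient_id")
    long = members.merge(
        clin[["time", "event"]], left_on="patient_id", right_index=True, how="left"
    )
    return MembershipAssignment(
        chosen_k=presence.k,
        chosen_threshold=float(tau),
        members=members,
        excluded_clusters=excluded,
        long_format=long.reset_index(drop=True),
    )


def andersen_gill_fit(
    assignment: MembershipAssignment,
    clinical: ClinicalTable | None = None,
    terms: list | None = None,
    reference: int | None = None,
) -> CoxFit:
    """Counting-process Cox fit over subpopulation memberships.

    One row per (patient, subpopulation) membership with the patient's time
    and event repeated; cluster-indicator dummies against a reference
    subpopulation (by default the largest); robust sandwich variance grouped
    by patient.  Wald p-values test each subpopulation against the
    reference.  Terms with fewer than 2 members are dropped with a note.
    """
    long = assignment.long_format.copy()
    counts = long.groupby("cluster").size()
    dropped = []
    small = counts[counts < 2].index.tolist()
    if small:
        dropped.append(f"clusters with <2 members dropped: {small}")
        long = long[~long["cluster"].isin(small)]
    clusters = sorted(long["cluster"].unique())
    if terms is not None:
        clusters = [c for c in clusters if c in set(terms) or c == reference]
    if len(clusters) < 2:
        raise ValueError("need at least 2 subpopulations with members to contrast")
    if reference is None:
        reference = int(counts.loc[clusters].idxmax())
    df = long[["time", "event", "patient_id"]].copy()
    for c in clusters:
        if c == reference:
            continue
        df[f"sub_{c}"] = (long["cluster"] == c).astype(int)
    fit = _lifelines_fit(df, robust=True, cluster_col="patient_id")
    out = _coxfit_from(fit, robust=True, cluster_col="patient_id", dropped=dropped)
    out.dropped.append(f"reference subpopulation: sub_{reference}")
    return out


def multivariate_cox(
    assignment: MembershipAssignment,
    clinical: ClinicalTable,
    stage_coding: str = "dummy",
) -> CoxFit:
    """Joint Cox model of subpopulations, stage, age and sex on survival.

    Subpopulation indicators are restricted to clusters with more than one
    member; a patient may switch on several of them (the reference state is
    "no retained subpopulation above threshold").  Stage enters as dummies
    against stage 1 by default, or as a single ordinal term with
    ``stage_coding='ordinal'``.  Collinear columns are dropped with a note.
    """
    clin = clinical.frame.set_index("patient_id")
    counts = assignment.counts()
    keep = counts[counts > 1].index.tolist()
    design = pd.DataFrame(index=clin.index)
    for c in keep:
        members = set(assignment.members_of(c))
        design[f"sub_{c}"] = [1 if p in members else 0 for p in design.index]
    if stage_coding == "dummy":
        for s in (2, 3, 4):
            design[f"stage_{s}"] = (clin["stage"] == s).astype(int)
    elif stage_coding == "ordinal":
        design["stage"] = clin["stage"].astype(float)
    else:
        raise ValueError("stage_coding must be 'dummy' or 'ordinal'")
    design["age"] = clin["age"].astype(float)
    design["sex_male"] = (clin["sex"].astype(str).str.upper().str.startswith("M")).astype(int)
    design, notes = _drop_collinear(design)
    df = pd.concat([clin[["time", "event"]], design], axis=1)
    fit = _lifelines_fit(df)
    out = _coxfit_from(fit, robust=False, cluster_col=None, dropped=notes)
    small = counts[counts <= 1].index.tolist()
    if small:
        out.dropped.append(f"single-member subpopulations excluded: {small}")
    return out


def pairwise_subpopulation_tests(fit: CoxFit, prefix: str = "sub_") -> pd.DataFrame:
    """Wald tests of all pairwise log-HR contrasts between subpopulation terms.

    Uses the fit's (robust, if fitted so) covariance matrix; the reference
    subpopulation enters with coefficient 0 only implicitly via the direct
    terms, so pairs listed are those with explicit coefficients.
    """
    terms = [t for t in fit.summary.index if t.startswith(prefix)]
    V = fit.variance_matrix
    rows = []
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            diff = fit.summary.loc[a, "coef"] - fit.summary.loc[b, "coef"]
            var = V.loc[a, a] + V.loc[b, b] - 2 * V.loc[a, b]
            se = float(np.sqrt(max(var, 0.0)))
            z = diff / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"term_a": a, "term_b": b, "coef_diff": diff, "se": se, "wald_p": p})
    return pd.DataFrame(rows)
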