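import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from msihet import (
    SyntheticConfig,
    andersen_gill_fit,
    assign_patients,
    cox_presence_aic,
    default_tau_grid,
    generate_cohort,
    grid_search,
    kmeans_segment,
    multivariate_cox,
    pairwise_subpopulation_tests,
    presence_matrix,
    rms_normalize,
    select_model,
)
from msihet.dataio import ClinicalTable
from msihet.segmentation import PresenceMatrix
from msihet.survgrid import GridResult, MembershipAssignment, null_partial_loglik


def _presence(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"P{i}" for i in range(len(rows))]
    frame = pd.DataFrame(rows, index=ids, columns=range(1, rows.shape[1] + 1))
    overall = frame.mean(axis=0)
    return PresenceMatrix(frame=frame, overall_shares=overall)


def _clinical(times, events, ids=None, stages=None, ages=None, sexes=None):
    n = len(times)
    ids = ids or [f"P{i}" for i in range(n)]
    return ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": ids,
                "time": times,
                "event": events,
                "stage": stages or [1 + i % 4 for i in range(n)],
                "age": ages or [50.0] * n,
                "sex": sexes or ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            }
        )
    )


def breslow_loglik(beta, time, event, x):
    """Brute-force Cox partial log-likelihood over explicit risk sets
    (no ties, single covariate)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCoxPresenceAic:
    def test_toy_fit_matches_risk_set_oracle(self):
        """4 patients, one binary covariate: the reported partial
        log-likelihood equals the hand-enumerated risk-set formula at the
        fitted coefficient, and AIC = 2p − 2ℓ.  (With covariate (1,1,0,0)
        the x=1 patients die first, so the likelihood is monotone and the
        row is additionally flagged degenerate.)"""
        pres = _presence([[1, 0], [1, 0], [0, 1], [0, 1]])
        clin = _clinical([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        fit, row = cox_presence_aic(pres, clin, 0.5)
        time = [1.0, 2.0, 3.0, 4.0]
        event = [1, 1, 1, 0]
        x = [1, 1, 0, 0]
        beta_hat = float(fit.summary["coef"].iloc[0])
        assert fit.loglik == pytest.approx(
            breslow_loglik(beta_hat, time, event, x), abs=1e-8
        )
        assert fit.n_params == 1
        assert row["aic"] == pytest.approx(2 * 1 - 2 * fit.loglik, abs=1e-8)
        assert row["degenerate"]  # monotone likelihood

    def test_toy_interior_optimum_matches_risk_set_oracle(self):
        """A variant with an interior maximum: fitted log-likelihood and AIC
        agree with brute-force maximization over explicit risk sets."""
        pres = _presence([[0, 1], [1, 0], [0, 1], [1, 0]])
        clin = _clinical([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        fit, row = cox_presence_aic(pres, clin, 0.5)
        time = [1.0, 2.0, 3.0, 4.0]
        event = [1, 1, 1, 0]
        x = [0, 1, 0, 1]
        opt = minimize_scalar(
            lambda b: -breslow_loglik(b, time, event, x),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-12},
        )
        assert fit.loglik == pytest.approx(-opt.fun, abs=1e-8)
        assert row["aic"] == pytest.approx(2 * 1 + 2 * opt.fun, abs=1e-8)
        assert not row["degenerate"]

    def test_no_varying_indicator_gives_null_model(self):
        pres = _presence([[0.9, 0.1]] * 4)
        clin = _clinical([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        fit, row = cox_presence_aic(pres, clin, 0.5)
        assert fit is None
        ll0 = null_partial_loglik(clin.frame["time"], clin.frame["event"])
        assert row["n_params"] == 0
        assert row["aic"] == pytest.approx(-2 * ll0)
        assert row["degenerate"]

    def test_null_loglik_hand_value(self):
        # 3 distinct deaths among 4 at-risk: -log4 - log3 - log2
        ll0 = null_partial_loglik([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        assert ll0 == pytest.approx(-(np.log(4) + np.log(3) + np.log(2)))

    def test_event_determining_indicator_flagged_degenerate(self):
        pres = _presence([[1, 0], [1, 0], [0, 1], [0, 1]])
        clin = _clinical([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
        _, row = cox_presence_aic(pres, clin, 0.5)
        assert row["degenerate"]
        assert "determines event status" in row["note"] or "monotone" in row["note"]

    def test_zero_events_is_error(self):
        pres = _presence([[1, 0], [0, 1]])
        clin = _clinical([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            cox_presence_aic(pres, clin, 0.5)


class TestGridSearchAndSelection:
    def test_grid_cardinality_and_aic_identity(self):
        rng = np.random.default_rng(0)
        pres = _presence(rng.dirichlet([1, 1, 1], size=30))
        clin = _clinical(list(rng.exponential(30, 30) + 0.5), list(rng.integers(0, 2, 30)))
        taus = np.array([0.1, 0.3])
        grid = grid_search({3: pres}, clin, taus)
        assert len(grid.frame) == 2
        for _, r in grid.frame.dropna(subset=["aic"]).iterrows():
            assert r["aic"] == pytest.approx(2 * r["n_params"] - 2 * r["loglik"], abs=1e-8)

    def test_results_independent_of_evaluation_order(self):
        rng = np.random.default_rng(1)
        pres = _presence(rng.dirichlet([1, 1, 1, 1], size=40))
        clin = _clinical(list(rng.exponential(30, 40) + 0.5), list(rng.integers(0, 2, 40)))
        taus = default_tau_grid(0.05, 0.45, 0.1)
        g1 = grid_search({4: pres}, clin, taus)
        g2 = grid_search({4: pres}, clin, taus[::-1])
        m1 = g1.frame.sort_values("threshold").reset_index(drop=True)
        m2 = g2.frame.sort_values("threshold").reset_index(drop=True)
        pd.testing.assert_frame_equal(m1, m2)

    def test_single_admissible_row_selected_and_all_degenerate_abstains(self):
        frame = pd.DataFrame(
            {
                "k": [3, 3, 4],
                "threshold": [0.1, 0.2, 0.1],
                "aic": [100.0, 90.0, 95.0],
                "loglik": [-49.0, -44.0, -46.5],
                "n_params": [1, 1, 1],
                "global_p": [0.2, 0.01, 0.4],
                "degenerate": [False, False, False],
                "n_assigned_clusters": [3, 3, 4],
                "note": [""] * 3,
            }
        )
        sel = select_model(GridResult(frame))
        assert sel.selected == (3, 0.2)
        frame2 = frame.assign(degenerate=True)
        sel2 = select_model(GridResult(frame2))
        assert sel2.abstained

    def test_aic_tie_broken_toward_smaller_k_then_tau(self):
        frame = pd.DataFrame(
            {
                "k": [5, 4, 4],
                "threshold": [0.1, 0.3, 0.2],
                "aic": [90.0, 90.0, 90.0],
                "loglik": [-44.0] * 3,
                "n_params": [1] * 3,
                "global_p": [0.01] * 3,
                "degenerate": [False] * 3,
                "n_assigned_clusters": [5, 4, 4],
                "note": [""] * 3,
            }
        )
        assert select_model(GridResult(frame)).selected == (4, 0.2)


class TestAssignment:
    def test_threshold_membership_examples(self):
        pres = _presence([[0.50, 0.30, 0.20], [0.95, 0.05, 0.0]], ids=["A", "B"])
        clin = _clinical([10.0, 20.0], [1, 0], ids=["A", "B"])
        asg = assign_patients(pres, 0.19, clin)
        assert set(map(tuple, asg.members.to_numpy())) == {
            ("A", 1), ("A", 2), ("A", 3), ("B", 1),
        }
        assert asg.excluded_clusters == []
        asg2 = assign_patients(pres, 0.6, clin)
        assert asg2.members.to_numpy().tolist() == [["B", 1]]
        assert asg2.excluded_clusters == [2, 3]

    def test_long_format_repeats_time_and_event(self):
        pres = _presence([[0.5, 0.5]], ids=["A"])
        clin = _clinical([7.0], [1], ids=["A"])
        asg = assign_patients(pres, 0.2, clin)
        assert len(asg.long_format) == 2
        assert set(asg.long_format["time"]) == {7.0}
        assert set(asg.long_format["event"]) == {1}


def _assignment(memberships, clin):
    members = pd.DataFrame(memberships, columns=["patient_id", "cluster"])
    long = members.merge(clin.frame[["patient_id", "time", "event"]], on="patient_id")
    return MembershipAssignment(
        chosen_k=int(members["cluster"].max()),
        chosen_threshold=0.2,
        members=members,
        excluded_clusters=[],
        long_format=long,
    )


class TestAndersenGill:
    def test_single_membership_reproduces_ordinary_cox(self):
        rng = np.random.default_rng(2)
        n = 40
        ids = [f"P{i}" for i in range(n)]
        grp = rng.integers(1, 3, n)
        clin = _clinical(list(rng.exponential(20, n) + 0.1), list(rng.integers(0, 2, n)), ids=ids)
        asg = _assignment(list(zip(ids, grp)), clin)
        ag = andersen_gill_fit(asg, clin)
        # ordinary Cox on the same patient-level data
        from lifelines import CoxPHFitter

        df = clin.frame[["time", "event"]].copy()
        other = 1 if f"sub_2" in ag.summary.index else 2
        term = [t for t in ag.summary.index if t.startswith("sub_")][0]
        df["x"] = (grp == int(term.split("_")[1])).astype(int)
        cph = CoxPHFitter().fit(df, "time", "event")
        assert ag.summary.loc[term, "coef"] == pytest.approx(cph.params_["x"], abs=1e-8)

    def test_identical_duplicated_groups_give_zero_contrast(self):
        """Every patient belongs to both subpopulations: the contrast between
        them is exactly null."""
        rng = np.random.default_rng(3)
        n = 20
        ids = [f"P{i}" for i in range(n)]
        clin = _clinical(list(rng.exponential(20, n) + 0.1), list(rng.integers(0, 2, n)), ids=ids)
        memberships = [(p, 1) for p in ids] + [(p, 2) for p in ids]
        ag = andersen_gill_fit(_assignment(memberships, clin), clin)
        term = [t for t in ag.summary.index if t.startswith("sub_")][0]
        assert ag.summary.loc[term, "coef"] == pytest.approx(0.0, abs=1e-6)
        assert ag.summary.loc[term, "wald_p"] == pytest.approx(1.0, abs=1e-3)

    def test_robust_variance_matches_sandwich_oracle(self):
        """Explicit score-residual sandwich on a 10-patient fixture (the two
        overlap patients are censored so event times stay untied)."""
        times = {"P1": 3.0, "P2": 5.0, "P3": 7.0, "P4": 11.0, "P5": 2.0,
                 "P6": 6.0, "P7": 9.0, "P8": 13.0, "P9": 4.0, "P10": 8.0}
        events = {"P1": 1, "P2": 1, "P3": 0, "P4": 1, "P5": 1, "P6": 1,
                  "P7": 1, "P8": 0, "P9": 0, "P10": 0}
        ids = list(times)
        clin = _clinical([times[p] for p in ids], [events[p] for p in ids], ids=ids)
        memberships = (
            [(p, 1) for p in ids[:4]]
            + [(p, 2) for p in ids[4:8]]
            + [(p, c) for p in ("P9", "P10") for c in (1, 2)]
        )
        asg = _assignment(memberships, clin)
        ag = andersen_gill_fit(asg, clin, reference=1)
        beta = float(ag.summary.loc["sub_2", "coef"])

        long = asg.long_format
        t = long["time"].to_numpy()
        d = long["event"].to_numpy()
        x = (long["cluster"] == 2).to_numpy(dtype=float)
        w = np.exp(beta * x)
        ev_times = np.sort(t[d == 1])
        S0 = {s: w[t >= s].sum() for s in ev_times}
        S1 = {s: (w * x)[t >= s].sum() for s in ev_times}
        S2 = {s: (w * x * x)[t >= s].sum() for s in ev_times}
        U = np.zeros(len(long))
        for j in range(len(long)):
            if d[j]:
                U[j] += x[j] - S1[t[j]] / S0[t[j]]
            for s in ev_times:
                if s <= t[j]:
                    U[j] -= w[j] * (x[j] - S1[s] / S0[s]) / S0[s]
        info = sum(S2[s] / S0[s] - (S1[s] / S0[s]) ** 2 for s in ev_times)
        g = pd.Series(U, index=long["patient_id"]).groupby(level=0).sum()
        se_oracle = float(np.sqrt((g**2).sum()) / info)
        assert ag.summary.loc["sub_2", "se"] == pytest.approx(se_oracle, abs=1e-6)

    def test_overlap_simulation_unbiased_with_nominal_coverage(self):
        """Marginal counting-process model with overlapping memberships among
        prognostically equivalent subpopulations: the A-vs-B log-HR contrast
        (truth 1.0) is estimated with small bias and ~95 % robust-CI
        coverage."""
        from scipy.stats import norm as normal

        n_rep = 200
        estimates = []
        covered = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            # 300 patients: 120 A, 100 B, 60 C, 20 B∩C; hazard e^1 for A
            ids = [f"P{i}" for i in range(300)]
            memberships = []
            lam = np.empty(300)
            for i, p in enumerate(ids):
                if i < 120:
                    memberships.append((p, 1))
                    lam[i] = 0.02 * np.e
                elif i < 220:
                    memberships.append((p, 2))
                    lam[i] = 0.02
                elif i < 280:
                    memberships.append((p, 3))
                    lam[i] = 0.02
                else:
                    memberships.append((p, 2))
                    memberships.append((p, 3))
                    lam[i] = 0.02
            t_ev = rng.exponential(1 / lam)
            t_c = rng.exponential(60, 300)
            tt = np.minimum(t_ev, t_c)
            ev = (t_ev <= t_c).astype(int)
            clin = _clinical(list(tt), list(ev), ids=ids)
            asg = _assignment(memberships, clin)
            ag = andersen_gill_fit(asg, clin, reference=3)
            V = ag.variance_matrix
            diff = ag.summary.loc["sub_1", "coef"] - ag.summary.loc["sub_2", "coef"]
            se = np.sqrt(
                V.loc["sub_1", "sub_1"] + V.loc["sub_2", "sub_2"] - 2 * V.loc["sub_1", "sub_2"]
            )
            estimates.append(diff)
            z = normal.ppf(0.975)
            covered += (diff - z * se) <= 1.0 <= (diff + z * se)
        assert abs(np.mean(estimates) - 1.0) <= 0.1
        assert 0.93 <= covered / n_rep <= 0.97


class TestMultivariateCox:
    def test_planted_effect_recovered_with_covariates(self):
        cfg = SyntheticConfig(
            n_patients=120, cores_per_patient=1, pixels_per_core=60, n_features=20,
            n_clusters_true=3, patches_per_core=10, centroid_separation=8.0,
            log_hazard_effects={1: 1.5}, composition_concentration=(1.0, 1.0, 1.0),
            seed=8,
        )
        pixels, clinical, _, truth = generate_cohort(cfg)
        seg = kmeans_segment(rms_normalize(pixels), 3, seed=0, n_init=3)
        pres = presence_matrix(seg, rms_normalize(pixels))
        asg = assign_patients(pres, cfg.presence_threshold_true, clinical)
        fit = multivariate_cox(asg, clinical)
        subs = fit.summary[fit.summary.index.str.startswith("sub_")]
        # the subpopulation matching the planted prognostic cluster carries
        # beta ~ 1.5 inside its own 95 % CI
        best = subs["coef"].idxmax()
        lo = np.log(subs.loc[best, "ci_low"])
        hi = np.log(subs.loc[best, "ci_high"])
        assert lo <= 1.5 <= hi
        for t in ("age", "sex_male"):
            assert t in fit.summary.index

    def test_single_member_subpopulations_excluded(self):
        ids = [f"P{i}" for i in range(12)]
        rng = np.random.default_rng(4)
        clin = _clinical(list(rng.exponential(20, 12) + 0.1), [1] * 12, ids=ids)
        memberships = [(p, 1) for p in ids[:11]] + [(ids[11], 2)]
        fit = multivariate_cox(_assignment(memberships, clin), clin)
        assert not any(t == "sub_2" for t in fit.summary.index)

    def test_pairwise_contrasts_consistent_with_fit(self):
        rng = np.random.default_rng(5)
        n = 60
        ids = [f"P{i}" for i in range(n)]
        grp = rng.integers(1, 4, n)
        clin = _clinical(list(rng.exponential(20, n) + 0.1), list(rng.integers(0, 2, n)), ids=ids)
        ag = andersen_gill_fit(_assignment(list(zip(ids, grp)), clin), clin, reference=3)
        pw = pairwise_subpopulation_tests(ag)
        assert len(pw) == 1  # sub_1 vs sub_2
        row = pw.iloc[0]
        assert row["coef_diff"] == pytest.approx(
            ag.summary.loc["sub_1", "coef"] - ag.summary.loc["sub_2", "coef"]
        )
        assert 0 <= row["wald_p"] <= 1
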