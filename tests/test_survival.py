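import numpy as np
import pandas as pd
import pytest

from airscore.prep import prepare_abundance
from airscore.survival import (
    MonotoneLikelihoodError,
    SeparationError,
    adjusted_association,
    bh_qvalues,
    classify_phenotype,
    cox_fit,
    differential_abundance,
    kaplan_meier,
    logistic_or,
    score_tertiles,
)
from airscore.synthetic import SimulationConfig, simulate_cohort


def grid_search_cox_beta(times, events, x, lo=-5.0, hi=5.0, n_grid=200_001):
    """Oracle: dense grid maximizer of the (no-ties) Cox partial likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    assert len(np.unique(times)) == len(times), "oracle assumes untied times"
    betas = np.linspace(lo, hi, n_grid)
    loglik = np.zeros(n_grid)
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ex = np.exp(betas[:, None] * x[None, risk])
        loglik += betas * x[i] - np.log(ex.sum(axis=1))
    return betas[np.argmax(loglik)]


class TestCoxFit:
    def test_monotone_likelihood_flagged(self):
        times = np.arange(1, 9, dtype=float)
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        with pytest.raises(MonotoneLikelihoodError):
            cox_fit(times, events, x)

    def test_matches_grid_search_oracle(self):
        # two groups, interleaved event times, no ties
        times = np.array(
            [0.7, 1.1, 1.6, 2.2, 2.9, 3.3, 3.8, 4.4, 4.9, 5.3, 5.6, 5.9,
             1.3, 1.9, 2.5, 3.1, 3.6, 4.1, 4.7, 5.1]
        )
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0,
                           1, 0, 1, 1, 0, 1, 1, 0])
        x = np.array([1.0] * 12 + [0.0] * 8)
        res = cox_fit(times, events, x)
        oracle = grid_search_cox_beta(times, events, x)
        assert res.beta == pytest.approx(oracle, abs=1e-4)

    def test_recovers_planted_hazard(self):
        cfg = SimulationConfig(
            n_children=2000, n_taxa=20, planted_taxa={3: float(np.log(1.45))}, seed=77
        )
        cohort = simulate_cohort(cfg)
        prepared, _ = prepare_abundance(cohort.abundance)
        res = cox_fit(
            cohort.survival["time_years"], cohort.survival["event"], prepared.values["g003"]
        )
        assert res.beta == pytest.approx(np.log(1.45), abs=0.08)
        assert res.ci95[0] < res.hr < res.ci95[1]

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(5, 60)
        events = (times < 6).astype(int)
        times = np.minimum(times, 6) + rng.random(60) * 1e-9
        x = rng.normal(size=60)
        b1 = cox_fit(times, events, x).beta
        b2 = cox_fit(times, events, 10 * x).beta
        assert b1 == pytest.approx(10 * b2, abs=1e-8 * abs(b1) + 1e-8)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])


class TestBH:
    def test_hand_stepup(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_test_identity(self):
        assert bh_qvalues([0.031])[0] == pytest.approx(0.031)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert np.allclose(bh_qvalues(p)[perm], bh_qvalues(p[perm]))

    def test_q_monotone_in_p(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        q = bh_qvalues(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()


class TestDifferentialAbundance:
    def test_sorted_and_fdr_columns(self, planted_cohort):
        prepared, _ = prepare_abundance(planted_cohort.abundance)
        table = differential_abundance(prepared.values, planted_cohort.survival)
        assert (np.diff(table["p"]) >= 0).all()
        assert (table["q"] >= table["p"] - 1e-12).all()
        # the strongest planted genus should reach the FDR threshold at n=600
        top_planted = set(planted_cohort.truth.planted_taxa)
        assert set(table.loc[table["q"] < 0.05, "taxon"]) & top_planted

    def test_sample_mismatch_errors(self, null_cohort):
        prepared, _ = prepare_abundance(null_cohort.abundance)
        bad = prepared.values.rename(index={prepared.values.index[0]: "ghost"})
        with pytest.raises(ValueError, match="ghost"):
            differential_abundance(bad, null_cohort.survival)


class TestAdjustedAssociation:
    def test_all_reference_covariates_equal_unadjusted(self):
        rng = np.random.default_rng(9)
        n = 120
        surv = pd.DataFrame(
            {
                "time_years": np.minimum(rng.exponential(8, n), 6.0),
                "event": 0,
                "paternal_asthma": 0,
                "older_siblings": 0,
                "season": "winter",
            },
            index=[f"c{i}" for i in range(n)],
        )
        surv["event"] = (surv["time_years"] < 6.0).astype(int)
        score = pd.Series(rng.normal(size=n), index=surv.index, name="s")
        adj = adjusted_association(score, surv)
        unadj = adjusted_association(score, surv, adjust=[])
        assert adj.beta == pytest.approx(unadj.beta, abs=1e-10)

    def test_adjustment_removes_confounding(self):
        rng = np.random.default_rng(4)
        closer = 0
        n_rep = 20
        truth = np.log(1.36)
        for _ in range(n_rep):
            n = 1000
            pat = (rng.random(n) < 0.3).astype(float)
            score = 1.5 * pat + rng.normal(size=n)
            score = (score - score.mean()) / score.std()
            eta = truth * score + 1.2 * pat
            t = rng.exponential(1 / (0.05 * np.exp(eta)))
            surv = pd.DataFrame(
                {
                    "time_years": np.minimum(t, 6.0),
                    "event": (t <= 6.0).astype(int),
                    "paternal_asthma": pat.astype(int),
                    "older_siblings": 0,
                    "season": "winter",
                },
                index=[f"c{i}" for i in range(n)],
            )
            s = pd.Series(score, index=surv.index, name="s")
            adj = adjusted_association(s, surv, adjust=["paternal_asthma"])
            unadj = adjusted_association(s, surv, adjust=[])
            closer += abs(adj.beta - truth) < abs(unadj.beta - truth)
        assert closer >= 0.9 * n_rep


class TestKaplanMeier:
    def test_no_events_zero_risk(self):
        km = kaplan_meier([6, 6, 6], [0, 0, 0], pd.Series(["g", "g", "g"]))
        assert km["g"]["risk_at_horizon"] == 0.0

    def test_product_limit_by_hand(self):
        # events at t=1 (risk set 4) and t=2 (risk set 3): S(2) = 3/4 * 2/3
        km = kaplan_meier([1, 2, 5, 6], [1, 1, 0, 0], pd.Series(["g"] * 4), horizon=2)
        assert km["g"]["risk_at_horizon"] == pytest.approx(1 - 0.5)

    def test_no_censoring_equals_empirical(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2, 200)
        km = kaplan_meier(t, np.ones(200, int), pd.Series(["g"] * 200), horizon=3.0)
        assert km["g"]["risk_at_horizon"] == pytest.approx((t <= 3.0).mean(), abs=1e-10)

    def test_tertile_sizes_573(self):
        score = pd.Series(np.random.default_rng(0).normal(size=573))
        sizes = score_tertiles(score).value_counts()
        assert tuple(sizes[["T1", "T2", "T3"]]) == (191, 191, 191)


class TestLogisticOr:
    def test_cross_product_ratio(self):
        y = np.array([1] * 10 + [1] * 20 + [0] * 20 + [0] * 10)
        x = np.array([1.0] * 10 + [0.0] * 20 + [1.0] * 20 + [0.0] * 10)
        res = logistic_or(y, pd.Series(x, name="x"))
        assert res["or"] == pytest.approx(0.25, rel=1e-4)

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(6)
        cover = 0
        n_rep = 50
        for _ in range(n_rep):
            y = (rng.random(400) < 0.3).astype(int)
            s = pd.Series(rng.normal(size=400), name="s")
            res = logistic_or(y, s)
            cover += res["ci95"][0] <= 1.0 <= res["ci95"][1]
        assert cover >= 0.85 * n_rep

    def test_perfect_predictor_raises(self):
        y = np.array([0] * 20 + [1] * 20)
        s = pd.Series(np.r_[np.zeros(20), np.ones(20)], name="s")
        with pytest.raises(SeparationError):
            logistic_or(y, s)


class TestPhenotypes:
    @pytest.mark.parametrize(
        "dx, remission, active, expected",
        [
            (2.0, True, False, {"transient_early"}),
            (2.5, False, True, {"persistent", "current_at_6"}),
            (4.0, False, True, {"late_onset", "current_at_6"}),
            (3.0, False, False, {"late_onset"}),  # boundary closed on late side
            (None, None, False, set()),
        ],
    )
    def test_labels(self, dx, remission, active, expected):
        assert classify_phenotype(dx, remission, active) == frozenset(expected)

    def test_inconsistent_flags(self):
        with pytest.raises(ValueError):
            classify_phenotype(2.0, True, True)

    def test_partition_of_asthma_cases(self):
        rng = np.random.default_rng(0)
        core = {"transient_early", "persistent", "late_onset"}
        for _ in range(200):
            dx = float(rng.uniform(0.1, 6.0))
            active = bool(rng.random() < 0.5)
            remission = False if active else bool(rng.random() < 0.5)
            labels = classify_phenotype(dx, remission, active)
            assert len(labels & core) == 1
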