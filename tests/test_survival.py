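import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from methclust import survival as S


class TestDichotomizeQ3:
    def test_interpolated_quantile_example(self):
        m = pd.DataFrame({"g": [1, 2, 3, 4, 5, 6, 7, 8]})
        binary = S.dichotomize_q3(m)
        assert binary["g"].sum() == 2  # values 7 and 8 exceed Q3 = 6.25
        assert binary["g"].tolist() == [0, 0, 0, 0, 0, 0, 1, 1]

    def test_quantile_landing_on_observation(self):
        m = pd.DataFrame({"g": [10, 20, 30, 40, 50]})
        binary = S.dichotomize_q3(m)  # Q3 = 40, strict > keeps only 50
        assert binary["g"].tolist() == [0, 0, 0, 0, 1]

    def test_constant_column_has_no_hm(self):
        m = pd.DataFrame({"g": [3.0] * 6})
        assert S.dichotomize_q3(m)["g"].sum() == 0

    def test_at_most_quarter_hm_with_distinct_values(self):
        rng = np.random.default_rng(0)
        for n in (4, 5, 8, 13, 40):
            m = pd.DataFrame({"g": rng.permutation(np.arange(n, dtype=float))})
            assert S.dichotomize_q3(m)["g"].sum() <= int(np.ceil(0.25 * n))

    def test_missing_values_rejected(self):
        m = pd.DataFrame({"g": [1.0, np.nan, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            S.dichotomize_q3(m)


def cox_binary_oracle(x, times, events):
    """Brute-force partial-likelihood maximizer for one binary covariate
    (no ties in event times)."""
    x = np.asarray(x, float)
    order = np.argsort(times)
    x, t, e = x[order], np.asarray(times, float)[order], np.asarray(events, int)[order]

    def neg_loglik(beta):
        ll = 0.0
        for i in range(len(t)):
            if e[i] == 1:
                risk = np.arange(len(t)) >= i  # later or equal times at risk
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-8, 8), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestPerGeneSurvival:
    def test_null_gene_hr_near_one(self):
        rng = np.random.default_rng(1)
        hrs = []
        for _ in range(6):
            hm = rng.integers(0, 2, size=120)
            t = rng.exponential(10, size=120)
            e = np.ones(120, int)
            hrs.append(S.per_gene_survival(hm, t, e).hazard_ratio)
        assert np.median(hrs) == pytest.approx(1.0, abs=0.25)

    def test_complete_separation_direction(self):
        # all HM die before any LM event; 6 vs 6, no censoring
        t = np.array([1, 2, 3, 4, 5, 6, 10, 11, 12, 13, 14, 15], float)
        hm = np.array([1] * 6 + [0] * 6)
        stat = S.per_gene_survival(hm, t, np.ones(12, int))
        assert stat.hazard_ratio > 1
        assert stat.logrank_p < 0.05

    def test_matches_partial_likelihood_oracle_n8(self):
        rng = np.random.default_rng(3)
        x = np.array([1, 0, 1, 0, 1, 0, 0, 1])
        t = rng.exponential(5, size=8) * np.where(x == 1, 0.4, 1.0)
        e = np.ones(8, int)
        stat = S.per_gene_survival(x, t, e)
        beta_oracle = cox_binary_oracle(x, t, e)
        assert np.log(stat.hazard_ratio) == pytest.approx(beta_oracle, abs=1e-6)

    def test_empty_group_unevaluable(self):
        stat = S.per_gene_survival([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])
        assert not stat.evaluable


class TestSelectClusterGenes:
    @staticmethod
    def _stat(gene, hr, p):
        return S.GeneSurvivalStat(gene, hr, p, 3, 9)

    def test_rule_application(self):
        stats = [self._stat("A", 1.8, 0.1), self._stat("B", 0.6, 0.05),
                 self._stat("C", 1.2, 0.25)]
        risk, protective = S.select_cluster_genes(stats)
        assert risk == ["A", "C"] and protective == ["B"]

    def test_high_p_excluded(self):
        stats = [self._stat("A", 1.8, 0.5), self._stat("B", 1.2, 0.1)]
        risk, _ = S.select_cluster_genes(stats)
        assert risk == ["B"]

    def test_all_protective_unevaluable(self):
        stats = [self._stat("A", 0.8, 0.1), self._stat("B", 0.5, 0.01)]
        with pytest.raises(S.UnevaluableCluster):
            S.select_cluster_genes(stats)


def youden_oracle(counts, dead):
    """Independent exhaustive maximizer of sens + spec - 1."""
    counts = np.asarray(counts, int)
    dead = np.asarray(dead, bool)
    best_c, best_j = None, -2.0
    for c in sorted({max(int(v), 1) for v in counts}):
        sens = np.mean(counts[dead] >= c)
        spec = np.mean(counts[~dead] < c)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    return best_c


class TestRocCutoff:
    def test_perfect_separation(self):
        counts = [3, 4, 5, 0, 1, 2]
        dead = [1, 1, 1, 0, 0, 0]
        assert S.roc_cutoff(counts, dead, n_boot=200, seed=0) == 3

    def test_bootstrap_disabled_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 13))
            counts = rng.integers(0, 6, size=n)
            dead = rng.integers(0, 2, size=n)
            if dead.all() or not dead.any():
                continue
            assert S.roc_cutoff(counts, dead, n_boot=1) == youden_oracle(counts, dead)
            checked += 1

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 9, size=60)
        dead = rng.integers(0, 2, size=60)
        a = S.roc_cutoff(counts, dead, n_boot=200, seed=42)
        b = S.roc_cutoff(counts, dead, n_boot=200, seed=42)
        assert a == b

    def test_single_status_rejected(self):
        with pytest.raises(ValueError):
            S.roc_cutoff([1, 2, 3], [1, 1, 1])


def logrank_oracle(t1, t0, e1, e0):
    """Hand event-table enumeration of the two-group log-rank statistic."""
    events = sorted({float(t) for t, e in zip(list(t1) + list(t0),
                                              list(e1) + list(e0)) if e == 1})
    t1, t0 = np.asarray(t1, float), np.asarray(t0, float)
    e1, e0 = np.asarray(e1, int), np.asarray(e0, int)
    o_minus_e, var = 0.0, 0.0
    for tau in events:
        n1 = np.sum(t1 >= tau)
        n0 = np.sum(t0 >= tau)
        d1 = np.sum((t1 == tau) & (e1 == 1))
        d0 = np.sum((t0 == tau) & (e0 == 1))
        n, d = n1 + n0, d1 + d0
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestStratifyKmLogrank:
    def test_identical_groups_statistic_zero(self):
        t = pd.Series([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = pd.Series([1, 1, 0, 1, 1, 1, 0, 1])
        counts = pd.Series([2, 2, 2, 2, 0, 0, 0, 0])
        strat = S.stratify_km_logrank(counts, 1, t, e)
        assert strat.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert strat.logrank_p == pytest.approx(1.0)

    def test_km_step_closed_form(self):
        n = 7
        # two low-count patients complete the second group without
        # touching the high group's product-limit curve
        t = pd.Series(np.r_[np.arange(1.0, n + 1), [50.0, 60.0]])
        e = pd.Series(np.ones(n + 2, int))
        counts = pd.Series([1] * n + [0, 0])
        strat = S.stratify_km_logrank(counts, 1, t, e)
        curve = strat.km_curves["high"].set_index("time")["survival"]
        for k in range(1, n + 1):
            assert curve.loc[float(k)] == pytest.approx((n - k) / n)

    def test_logrank_matches_event_table_oracle(self):
        rng = np.random.default_rng(8)
        t = pd.Series(rng.exponential(5, size=12).round(3))
        e = pd.Series(rng.integers(0, 2, size=12))
        e.iloc[:4] = 1  # ensure events exist
        counts = pd.Series([1] * 6 + [0] * 6)
        strat = S.stratify_km_logrank(counts, 1, t, e)
        high = counts >= 1
        expected = logrank_oracle(t[high], t[~high], e[high], e[~high])
        assert strat.logrank_stat == pytest.approx(expected, rel=1e-9)

    def test_empty_group_suggests_other_cutoff(self):
        with pytest.raises(S.UnevaluableCluster, match="cutoff"):
            S.stratify_km_logrank(pd.Series([0, 0, 0, 0]), 1,
                                  pd.Series([1.0, 2, 3, 4]),
                                  pd.Series([1, 1, 1, 1]))


class TestCoxFit:
    def test_single_binary_covariate_matches_oracle_n8(self):
        rng = np.random.default_rng(21)
        x = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        t = rng.exponential(4, size=8) * np.where(x == 1, 0.5, 1.0)
        e = np.ones(8, int)
        res = S.cox_fit(x, t, e)
        beta_oracle = cox_binary_oracle(x, t, e)
        assert np.log(res.table.loc["group", "hr"]) == pytest.approx(
            beta_oracle, abs=1e-6
        )

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(22)
        covered = 0
        n_rep = 20
        for _ in range(n_rep):
            x = rng.integers(0, 2, size=150)
            t = rng.exponential(10, size=150)
            e = (rng.random(150) < 0.8).astype(int)
            res = S.cox_fit(x, t, e)
            row = res.table.loc["group"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= int(0.8 * n_rep)

    def test_covariate_table_shape_and_invariants(self):
        rng = np.random.default_rng(23)
        n = 120
        x = rng.integers(0, 2, size=n)
        age = rng.normal(60, 8, size=n)
        grade = rng.integers(1, 4, size=n)
        er = rng.choice(["positive", "negative", "unknown"], size=n)
        t = rng.exponential(10, size=n) * np.exp(-0.5 * x)
        e = np.ones(n, int)
        res = S.cox_fit(x, t, e, age=age, grade=grade, er_status=er)
        assert set(res.table.index) == {"group", "age", "grade", "er_positive"}
        assert res.n == int(np.sum(er != "unknown"))
        for _, row in res.table.iterrows():
            assert row["ci_low"] <= row["hr"] <= row["ci_high"]
            assert row["hr"] > 0


class TestEndToEndStratification:
    def test_planted_cluster_detected_null_calibrated(self):
        """Selection-free recovery: the planted cluster separates survival,
        the null cluster does not, and label permutation destroys the
        planted signal."""
        import methclust as mc

        sig_planted, sig_null, perm_ps = [], [], []
        for seed in range(5):
            cfg = mc.SimulationConfig(seed=300 + seed, n_tumor=200,
                                      background_slots=0)
            cohort = mc.simulate_cohort(cfg, with_reads=False)
            tumors = [s for s in cohort.samples if s.group == "tumor"]
            ids = [s.sample_id for s in tumors]
            times = pd.Series([s.os_time for s in tumors], index=ids)
            events = pd.Series([s.os_event for s in tumors], index=ids)
            meth = cohort.methylation.loc[ids]
            clusters = {}
            for g in cohort.annotation.genes:
                if g.cluster_id:
                    clusters.setdefault(g.cluster_id, []).append(g.gene_id)
            for cid, sink in (("cluster_1", sig_planted), ("cluster_2", sig_null)):
                strat = S.analyze_cluster(meth, clusters[cid], times, events,
                                          n_boot=50, seed=seed,
                                          select_genes=False)
                sink.append(strat.logrank_p)
            # permuting survival times against the planted grouping
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(ids))
            strat = S.analyze_cluster(
                meth, clusters["cluster_1"],
                pd.Series(times.to_numpy()[perm], index=ids),
                pd.Series(events.to_numpy()[perm], index=ids),
                n_boot=50, seed=seed, select_genes=False,
            )
            perm_ps.append(strat.logrank_p)
        assert sum(p < 0.05 for p in sig_planted) >= 4
        assert sum(p < 0.05 for p in sig_null) <= 1
        assert np.median(perm_ps) > 0.1
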