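"""Survival machinery, multiplicity control, and the test-selection tree."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tcatrace.cohort_stats import (
    Endpoint,
    SurvivalRecord,
    auto_select_test,
    cox_binary,
    holm_sidak_adjust,
    km_fit,
    kruskal_wallis_dunn,
    logrank_test,
    metabolite_survival_screen,
    spearman_matrix,
    wilcoxon_signed_rank,
)
from tcatrace.metrics import GroupLabel


def recs(times, events, prefix="p"):
    return [
        SurvivalRecord(f"{prefix}{i}", t, bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_fit(recs([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(curve.survival_probs, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [4, 3, 2, 1])

    def test_all_censored_stays_at_one(self):
        curve = km_fit(recs([5, 8, 13], [0, 0, 0]))
        np.testing.assert_allclose(curve.survival_probs, 1.0)

    def test_manual_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S(1) = 2/3, S(3) = (2/3)*(0/1) = 0
        curve = km_fit(recs([1, 2, 3], [1, 0, 1]))
        s = dict(zip(curve.event_times, curve.survival_probs))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_empirical_survival_property_random_uncensored(self, rng):
        times = rng.exponential(10, size=25).round(3)
        curve = km_fit(recs(times, np.ones(25)))
        for t, s in zip(curve.event_times, curve.survival_probs):
            assert s == pytest.approx(np.mean(times > t))

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            km_fit([])


def hand_logrank(group_a, group_b):
    """Independent O-E/V computation of the Mantel-Cox statistic."""
    all_recs = [(r.time, r.event, 0) for r in group_a] + [
        (r.time, r.event, 1) for r in group_b
    ]
    event_times = sorted({t for t, e, _ in all_recs if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n = sum(1 for tt, _, _ in all_recs if tt >= t)
        n_a = sum(1 for tt, _, g in all_recs if tt >= t and g == 0)
        d = sum(1 for tt, e, _ in all_recs if tt == t and e)
        d_a = sum(1 for tt, e, g in all_recs if tt == t and e and g == 0)
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_chi2_zero(self):
        a = recs([1, 2, 3, 4], [1, 1, 0, 1], "a")
        b = recs([1, 2, 3, 4], [1, 1, 0, 1], "b")
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_o_minus_e_on_toy(self):
        a = recs([2, 5, 7, 11], [1, 1, 0, 1], "a")
        b = recs([1, 3, 6, 9], [1, 1, 1, 0], "b")
        chi2, _ = logrank_test(a, b)
        assert chi2 == pytest.approx(hand_logrank(a, b), rel=1e-9)

    def test_label_swap_invariance_and_time_rescaling(self):
        a = recs([2, 5, 7], [1, 1, 0], "a")
        b = recs([1, 3, 6, 9], [1, 1, 1, 0], "b")
        chi2_ab, p_ab = logrank_test(a, b)
        chi2_ba, _ = logrank_test(b, a)
        assert chi2_ab == pytest.approx(chi2_ba)
        a12 = recs([24, 60, 84], [1, 1, 0], "a")
        b12 = recs([12, 36, 72, 108], [1, 1, 1, 0], "b")
        _, p_scaled = logrank_test(a12, b12)
        assert p_scaled == pytest.approx(p_ab)

    def test_zero_events_returns_missing_with_warning(self):
        a = recs([1, 2], [0, 0], "a")
        b = recs([3, 4], [0, 0], "b")
        with pytest.warns(UserWarning):
            chi2, p = logrank_test(a, b)
        assert math.isnan(chi2) and math.isnan(p)


def breslow_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single binary covariate."""
    ll = 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        at_risk = [i for i, tt in enumerate(times) if tt >= t]
        deaths = [i for i, (tt, e) in enumerate(zip(times, events)) if tt == t and e]
        risk_sum = sum(math.exp(beta * x[i]) for i in at_risk)
        for i in deaths:
            ll += beta * x[i] - math.log(risk_sum)
    return ll


def grid_argmax_beta(times, events, x):
    grid = np.arange(-4.0, 4.0, 1e-3)
    lls = [breslow_partial_loglik(b, times, events, x) for b in grid]
    return grid[int(np.argmax(lls))]


class TestCoxBinary:
    @staticmethod
    def groups_from(x, pids):
        return [
            GroupLabel(p, "high" if xi else "low", "score", 0.0)
            for p, xi in zip(pids, x)
        ]

    def test_symmetric_data_gives_hr_one(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        x = [1, 1, 1, 1, 0, 0, 0, 0]
        pids = [f"p{i}" for i in range(8)]
        res = cox_binary(recs(times, events), self.groups_from(x, pids))
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_coefficient_matches_grid_search_argmax(self, rng):
        n = 18
        times = rng.exponential(10, n).round(2) + 0.1
        events = rng.random(n) < 0.7
        x = (rng.random(n) < 0.5).astype(int)
        if events[x == 1].sum() == 0 or events[x == 0].sum() == 0:
            pytest.fail("fixture needs events in both groups")
        pids = [f"p{i}" for i in range(n)]
        res = cox_binary(recs(times, events), self.groups_from(x, pids))
        beta_grid = grid_argmax_beta(list(times), list(events), list(x))
        assert abs(math.log(res.hazard_ratio) - beta_grid) < 1e-3

    def test_reference_is_low_group(self, rng):
        # high group with mostly shorter survival -> HR > 1
        times = [1, 2, 5, 3, 11, 12]
        events = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        pids = [f"p{i}" for i in range(6)]
        res = cox_binary(recs(times, events), self.groups_from(x, pids))
        assert res.hazard_ratio > 1
        assert res.ci95[0] <= res.hazard_ratio <= res.ci95[1]

    def test_no_events_in_one_group_flags_infinite_bound(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 0, 0, 0]
        x = [1, 1, 1, 0, 0, 0]
        pids = [f"p{i}" for i in range(6)]
        with pytest.warns(UserWarning):
            res = cox_binary(recs(times, events), self.groups_from(x, pids))
        assert res.infinite_bound
        assert math.isinf(res.hazard_ratio)


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_sidak_adjust([0.04]), [0.04])

    def test_closed_form_example(self):
        adj = holm_sidak_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(np.round(adj, 4), [0.0297, 0.0396, 0.0396])

    def test_adjusted_at_least_raw_and_bounded(self, rng):
        p = rng.random(20)
        adj = holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone in the order statistics
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_restores_input_order(self):
        p = np.array([0.5, 0.001, 0.2])
        adj = holm_sidak_adjust(p)
        assert adj[1] == adj.min()


class TestWilcoxonSignedRank:
    def test_all_ties_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank(a, a)
        assert p == 1.0

    def test_exact_p_matches_full_enumeration_n5(self, rng):
        for _ in range(5):
            d = rng.normal(0.4, 1.0, 5)
            d = d[d != 0]
            a = d
            b = np.zeros_like(d)
            w_obs, p = wilcoxon_signed_rank(a, b)
            # literal 2^n enumeration oracle
            from scipy.stats import rankdata

            ranks = rankdata(np.abs(d))
            total = ranks.sum()
            ws = [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=len(d))
            ]
            dev = abs(w_obs - total / 2)
            p_enum = np.mean([abs(w - total / 2) >= dev - 1e-9 for w in ws])
            assert p == pytest.approx(p_enum)

    def test_exact_and_normal_branches_agree_near_threshold(self, rng):
        a = rng.normal(0.5, 1, 30)
        b = rng.normal(0.0, 1, 30)
        _, p_exact = wilcoxon_signed_rank(a, b, exact_threshold=40)
        _, p_approx = wilcoxon_signed_rank(a, b, exact_threshold=10)
        assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_power_on_simulated_tumor_lung_shift(self):
        # paired tumor/lung with tumor PDH fraction shifted +0.2
        from tcatrace.metrics import tca_total_score
        from tcatrace.tca_sim import CohortSimConfig, generate_patient

        cfg = CohortSimConfig(noise_sd=0.002)
        rng = np.random.default_rng(5)
        hits = 0
        n_reps = 20  # scaled-down spot check; acceptance runs the full design
        for rep in range(n_reps):
            tumors, lungs = [], []
            for i in range(30):
                lung_a = rng.uniform(0.05, 0.25)
                t, l = generate_patient(lung_a + 0.2, lung_a, cfg, rng, f"P{i}")
                tumors.append(tca_total_score(t))
                lungs.append(tca_total_score(l))
            _, p = wilcoxon_signed_rank(tumors, lungs)
            hits += p < 0.01
        assert hits >= 19


class TestKruskalWallisDunn:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        h, p, pairwise = kruskal_wallis_dunn([g, g, g])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99
        assert (pairwise["p_adjusted"] > 0.99).all()

    def test_h_matches_hand_rank_formula_with_ties(self):
        groups = [[1.0, 2.0, 2.0], [3.0, 5.0, 4.0], [6.0, 7.0, 2.0]]
        h, _, _ = kruskal_wallis_dunn(groups)
        from scipy.stats import rankdata

        pooled = np.concatenate(groups)
        ranks = rankdata(pooled)
        n = pooled.size
        start, h_hand = 0, 0.0
        for g in groups:
            r = ranks[start : start + len(g)]
            h_hand += r.sum() ** 2 / len(g)
            start += len(g)
        h_hand = 12 / (n * (n + 1)) * h_hand - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        h_hand /= 1 - ((counts**3 - counts).sum()) / (n**3 - n)
        assert h == pytest.approx(h_hand, rel=1e-9)

    def test_pairwise_significance_follows_shift_magnitude(self, rng):
        base = rng.normal(0, 1, 30)
        groups = [base, base + 1.0, base + 4.0]
        _, _, pairwise = kruskal_wallis_dunn(groups, ["g0", "g1", "g2"])
        pw = pairwise.set_index(["group_a", "group_b"])["p_adjusted"]
        assert pw[("g0", "g2")] < pw[("g0", "g1")]
        assert pw[("g0", "g2")] < 0.001

    def test_fewer_than_three_groups_redirects(self):
        with pytest.raises(ValueError, match="two-group"):
            kruskal_wallis_dunn([[1.0, 2.0], [3.0, 4.0]])


class TestSpearmanMatrix:
    def test_monotone_relations(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "double": 2 * x, "negcube": -(x**3)})
        res = spearman_matrix(df, ["x", "double", "negcube"])
        rho = dict(zip(res.pairs, res.rho))
        assert rho[("x", "double")] == pytest.approx(1.0)
        assert rho[("x", "negcube")] == pytest.approx(-1.0)

    def test_constant_feature_gives_missing(self):
        df = pd.DataFrame({"x": np.arange(8.0), "c": np.ones(8)})
        res = spearman_matrix(df, ["x", "c"])
        assert math.isnan(res.rho[0])

    def test_simulated_cohort_m2_correlations(self):
        from tcatrace.metrics import (
            TissueClass,
            compute_sample_metrics,
            metrics_table,
        )
        from tcatrace.tca_sim import CohortSimConfig, generate_cohort

        samples, _ = generate_cohort(CohortSimConfig(n_patients=50, seed=2))
        tumors = [s for s in samples if s.tissue_class == TissueClass.TUMOR]
        table = metrics_table([compute_sample_metrics(s) for s in tumors])
        res = spearman_matrix(table, ["m2_norm_citrate", "m2_norm_malate"])
        assert res.rho[0] > 0.8


class TestAutoSelectTest:
    def test_gaussian_equal_variance_takes_student_t(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        name, p, log2 = auto_select_test(a, b)
        assert name == "student_t" and not log2 and 0 <= p <= 1

    def test_lognormal_takes_log2_parametric_branch(self):
        rng = np.random.default_rng(3)
        a = np.exp(rng.normal(0, 1.2, 40))
        b = np.exp(rng.normal(0.3, 1.2, 40))
        name, _, log2 = auto_select_test(a, b)
        assert log2 and name in ("student_t", "welch_t")

    def test_heavy_tailed_with_negatives_takes_nonparametric(self):
        rng = np.random.default_rng(8)
        a = rng.standard_cauchy(30)
        b = rng.standard_cauchy(30) + 1
        name, _, log2 = auto_select_test(a, b)
        assert name == "mann_whitney" and not log2

    def test_paired_gaussian_takes_paired_t(self, rng):
        a = rng.normal(0, 1, 12)
        b = a + rng.normal(0.3, 0.2, 12)
        name, _, _ = auto_select_test(a, b, paired=True)
        assert name == "paired_t"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            auto_select_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMetaboliteSurvivalScreen:
    @staticmethod
    def make_survival(rng, hazards):
        times = rng.exponential(1.0 / hazards)
        censor = rng.exponential(40, size=hazards.size)
        return [
            SurvivalRecord(f"p{i}", max(min(t, c), 1e-3), t <= c)
            for i, (t, c) in enumerate(zip(times, censor))
        ]

    def test_null_simulation_controls_fdr(self, rng):
        n, m = 60, 150  # scaled-down feature count; acceptance runs 600
        abundances = pd.DataFrame(
            rng.lognormal(0, 1, (n, m)),
            index=[f"p{i}" for i in range(n)],
            columns=[f"met{j}" for j in range(m)],
        )
        records = self.make_survival(rng, np.full(n, 0.03))
        res = metabolite_survival_screen(abundances, records)
        assert (res["p_adjusted"] < 0.05).sum() <= max(1, int(0.05 * m))

    def test_spiked_feature_ranks_first(self, rng):
        n = 80
        risk = rng.normal(0, 1, n)
        abundances = pd.DataFrame(
            rng.lognormal(0, 1, (n, 30)),
            index=[f"p{i}" for i in range(n)],
            columns=[f"met{j}" for j in range(30)],
        )
        abundances["driver"] = np.exp(risk)
        hazards = 0.02 * np.exp(1.5 * risk)
        records = self.make_survival(rng, hazards)
        res = metabolite_survival_screen(abundances, records)
        assert res.iloc[0]["feature"] == "driver"

    def test_single_feature_bh_is_identity(self, rng):
        n = 20
        abundances = pd.DataFrame(
            rng.lognormal(0, 1, (n, 1)),
            index=[f"p{i}" for i in range(n)],
            columns=["met0"],
        )
        records = self.make_survival(rng, np.full(n, 0.05))
        res = metabolite_survival_screen(abundances, records)
        assert res["p_adjusted"].iloc[0] == pytest.approx(res["p_raw"].iloc[0])


class TestNullCalibration:
    def test_logrank_type_one_error_spot_check(self, rng):
        # 300-rep spot check at n=33/33; acceptance runs the full 1000
        rej = 0
        n_reps = 300
        for _ in range(n_reps):
            a = recs(rng.exponential(50, 33), np.ones(33), "a")
            b = recs(rng.exponential(50, 33), np.ones(33), "b")
            rej += logrank_test(a, b)[1] < 0.05
        assert 0.02 <= rej / n_reps <= 0.08
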