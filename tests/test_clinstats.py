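from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from nbsubtype import (ClinicalTable, ClusterAssignment, anova_oneway,
                       assign_genomic_subtype, cluster_factor_enrichment,
                       crosstab, fisher_exact, five_year_fisher,
                       genomic_subtypes, km_curve, logrank, pearson,
                       survival_at, tukey_posthoc, welch_t)
from nbsubtype.clinstats import ContingencyTable2x2, km_by_cluster


def hypergeom_two_sided(a, b, c, d):
    """Independent oracle: exhaustive enumeration over tables with the
    observed margins; two-sided p sums probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(X = x) for X ~ Hypergeom(n, r1, c1)
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-12))


class TestFisherExact:
    def test_no_association(self):
        assert fisher_exact(ContingencyTable2x2(2, 2, 2, 2)) == 1.0

    def test_perfect_association(self):
        p = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact(ContingencyTable2x2(3, 2, 0, 0)) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 2, 2)

    @pytest.mark.parametrize("table", [(1, 2, 3, 4), (5, 1, 0, 6),
                                       (2, 5, 4, 1), (3, 3, 3, 3)])
    def test_matches_enumeration_oracle(self, table):
        p = fisher_exact(ContingencyTable2x2(*table))
        assert p == pytest.approx(hypergeom_two_sided(*table), abs=1e-12)


class TestEnrichment:
    def _cohort(self, n_per_group=15, mna_group=3, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(4 * n_per_group)]
        labels = pd.Series(np.repeat([1, 2, 3, 4], n_per_group), index=ids)
        df = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
        df["inss_stage"] = "3"
        for f in ("mna", "del1p", "del11q", "del3p", "gain17q", "dod"):
            df[f] = 0.0
        df.loc[labels == mna_group, "mna"] = 1.0
        df["os_time"] = rng.uniform(10, 100, len(ids))
        df["os_event"] = 0.0
        df["efs_time"] = df["os_time"]
        df["efs_event"] = 0.0
        return ClusterAssignment.from_labels(labels, "pca"), ClinicalTable(df)

    def test_planted_mna_enrichment(self):
        assign, clin = self._cohort()
        table = cluster_factor_enrichment(assign, clin, factors=("mna",))
        assert table.loc["mna", 3] < 0.01
        assert table.loc["mna", 1] < 0.05  # depletion is two-sided significant

    def test_factor_present_everywhere_gives_one(self):
        assign, clin = self._cohort()
        clin.data["gain17q"] = 1.0
        table = cluster_factor_enrichment(assign, clin, factors=("gain17q",))
        assert (table.loc["gain17q"] == 1.0).all()

    def test_unknowns_never_counted(self):
        assign, clin = self._cohort()
        # blank MNA outside group 3: tables shrink, conclusion unchanged
        out = clin.data.copy()
        mask = assign.labels == 1
        out.loc[mask, "mna"] = np.nan
        table = cluster_factor_enrichment(assign, ClinicalTable(out),
                                          factors=("mna",))
        # oracle on the reduced counts: group 3 = 15/15 MNA, rest 0/30 known
        assert table.loc["mna", 3] == pytest.approx(
            hypergeom_two_sided(15, 0, 0, 30), abs=1e-12)

    def test_entirely_unknown_factor_rejected(self):
        assign, clin = self._cohort()
        clin.data["del3p"] = np.nan
        with pytest.raises(ValueError, match="unknown"):
            cluster_factor_enrichment(assign, clin, factors=("del3p",))


class TestAnovaWelchPearson:
    def test_identical_constant_groups(self):
        values = pd.Series([5.0] * 9, index=[f"s{i}" for i in range(9)])
        labels = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3], index=values.index)
        f, p = anova_oneway(values, labels)
        assert (f, p) == (0.0, 1.0)

    def test_two_groups_f_is_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        values = pd.Series(np.concatenate([a, b]),
                           index=[f"s{i}" for i in range(14)])
        labels = pd.Series([1] * 8 + [2] * 6, index=values.index)
        f, _ = anova_oneway(values, labels)
        sp2 = ((7 * a.var(ddof=1) + 5 * b.var(ddof=1)) / 12)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 8 + 1 / 6))
        assert f == pytest.approx(t ** 2, rel=1e-10)

    def test_f_matches_sum_of_squares_oracle(self, rng):
        groups = [rng.normal(m, 1, 5) for m in (0, 1, 3)]
        values = pd.Series(np.concatenate(groups),
                           index=[f"s{i}" for i in range(15)])
        labels = pd.Series(np.repeat([1, 2, 3], 5), index=values.index)
        f, _ = anova_oneway(values, labels)
        grand = values.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / 12)
        assert f == pytest.approx(f_oracle, rel=1e-10)

    def test_small_group_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        labels = pd.Series([1, 1, 2], index=values.index)
        with pytest.raises(ValueError, match="at least 2"):
            anova_oneway(values, labels)

    def test_tukey_flags_the_separated_group(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(0.1, 1, 6), rng.normal(8, 1, 6)]
        values = pd.Series(np.concatenate(groups),
                           index=[f"s{i}" for i in range(18)])
        labels = pd.Series(np.repeat([1, 2, 3], 6), index=values.index)
        table = tukey_posthoc(values, labels)
        assert table.loc[1, 3] < 0.001 and table.loc[2, 3] < 0.001
        assert table.loc[1, 2] > 0.1

    def test_welch_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_welch_reduces_to_pooled_t_balanced_equal_variance(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + 0.8  # same sample variance, shifted mean
        t, p = welch_t(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t_pooled = (a.mean() - b.mean()) / np.sqrt(sp2 * 0.2)
        import scipy.stats as st
        p_pooled = 2 * st.t.sf(abs(t_pooled), 18)
        assert t == pytest.approx(t_pooled, rel=1e-10)
        assert p == pytest.approx(p_pooled, rel=1e-6)

    def test_welch_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(2, 3, 9)
        t1, p1 = welch_t(a, b)
        t2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_pearson_limits_and_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)
        y = np.array([2.0, 1.0, 3.0, 7.0, 4.0])
        r, _ = pearson(x, y)
        r_oracle = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(r_oracle, rel=1e-12)
        with pytest.raises(ValueError, match="constant"):
            pearson(x, np.ones(5))


class TestSurvival:
    def test_all_events_product_limit_by_hand(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_by_hand(self):
        # event at 1 (3 at risk), censor at 2, event at 3 (1 at risk)
        curve = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 2 / 3, 0.0])

    def test_no_events_curve_stays_at_one(self):
        curve = km_curve(np.linspace(1, 80, 14), np.zeros(14))
        assert (curve.survival == 1.0).all()
        assert survival_at(curve, 60.0) == 1.0

    def test_survival_at_before_first_event(self):
        curve = km_curve([10.0, 20.0], [1, 1])
        assert survival_at(curve, 5.0) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([], [])

    def test_logrank_identical_groups_null(self):
        g = ([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        chi2, p = logrank([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_logrank_matches_hand_tabulated_oe(self):
        # two groups, six subjects, all events, no ties
        t1, t2 = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        chi2, _ = logrank([(t1, [1, 1, 1]), (t2, [1, 1, 1])])
        # hand O-E: walk event times, expected = at_risk1 / at_risk_total
        at_risk1, at_risk2 = 3, 3
        o_minus_e, var = 0.0, 0.0
        for t in sorted(t1 + t2):
            n = at_risk1 + at_risk2
            e1 = at_risk1 / n
            d1 = 1 if t in t1 else 0
            o_minus_e += d1 - e1
            if n > 1:
                var += at_risk1 * at_risk2 * (n - 1) / (n ** 2 * (n - 1))
            if d1:
                at_risk1 -= 1
            else:
                at_risk2 -= 1
        assert chi2 == pytest.approx(o_minus_e ** 2 / var, rel=1e-9)

    def test_logrank_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank([([1.0, 2.0], [0, 0]), ([3.0], [0])])

    def test_five_year_all_alive(self):
        ids = [f"s{i}" for i in range(8)]
        labels = ClusterAssignment.from_labels(
            pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=ids), "pca")
        df = pd.DataFrame({"os_time": 70.0, "os_event": 0.0}, index=ids)
        clin = ClinicalTable(df)
        assert (five_year_fisher(labels, clin) == 1.0).all()

    def test_five_year_censored_early_excluded(self):
        ids = [f"s{i}" for i in range(6)]
        labels = ClusterAssignment.from_labels(
            pd.Series([1, 1, 1, 2, 2, 2], index=ids), "pca")
        df = pd.DataFrame({
            "os_time": [70.0, 12.0, 70.0, 70.0, 24.0, 70.0],
            "os_event": [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],  # s4 censored at 24
        }, index=ids)
        p = five_year_fisher(labels, ClinicalTable(df))
        # counts: cluster1 dead 1 alive 2; cluster2 dead 0 alive 2 (s4 out)
        assert p[1] == pytest.approx(hypergeom_two_sided(1, 0, 2, 2), abs=1e-12)

    def test_km_by_cluster_drops_unknown_times(self):
        ids = [f"s{i}" for i in range(5)]
        labels = ClusterAssignment.from_labels(
            pd.Series([1, 1, 1, 2, 2], index=ids), "pca")
        df = pd.DataFrame({
            "os_time": [10.0, np.nan, 30.0, 5.0, 6.0],
            "os_event": [1.0, np.nan, 0.0, 1.0, 1.0],
        }, index=ids)
        curves = km_by_cluster(labels, ClinicalTable(df))
        assert curves[1].at_risk[0] == 2


class TestGenomicSubtypes:
    def _row(self, stage="1", mna=0, del11q=0, del1p=0, del3p=0, dod=0):
        return pd.Series({"inss_stage": stage, "mna": mna, "del11q": del11q,
                          "del1p": del1p, "del3p": del3p, "dod": dod})

    def test_mna_always_type2b(self):
        assert assign_genomic_subtype(self._row(stage="4", mna=1)) == "Type2B"

    def test_del11q_without_mna_type2a(self):
        assert assign_genomic_subtype(self._row(mna=0, del11q=1)) == "Type2A"

    def test_low_stage_clean_alive_type1(self):
        assert assign_genomic_subtype(self._row(stage="2")) == "Type1"

    def test_stage4_without_markers_other(self):
        assert assign_genomic_subtype(self._row(stage="4")) == "Other"

    def test_unknown_flag_sends_to_other(self):
        assert assign_genomic_subtype(
            self._row(stage="2", mna=np.nan)) == "Other"

    def test_total_function_over_tristates(self):
        labels = {"Type1", "Type2A", "Type2B", "Other"}
        tri = (0, 1, np.nan)
        for stage, mna, d11, d1p, dod in product(
                ("1", "3", "4", "4S", "unknown"), tri, tri, tri, tri):
            row = self._row(stage=stage, mna=mna, del11q=d11, del1p=d1p, dod=dod)
            assert assign_genomic_subtype(row) in labels


class TestCrosstab:
    def test_single_cell(self):
        ids = ["a", "b", "c"]
        assign = ClusterAssignment.from_labels(
            pd.Series([1, 1, 1], index=ids), "pca")
        subtypes = pd.Series(["Type1"] * 3, index=ids)
        tab = crosstab(assign, subtypes)
        assert tab.loc["Type1", 1] == 3
        assert tab.to_numpy().sum() == 3

    def test_counts_conserved(self, small_clinical):
        ids = small_clinical.samples
        assign = ClusterAssignment.from_labels(
            pd.Series([1, 2, 1, 2, 1, 2], index=ids), "pca")
        tab = crosstab(assign, genomic_subtypes(small_clinical))
        assert tab.to_numpy().sum() == 6
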