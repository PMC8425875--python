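import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mpinet.stats import (
    ExpressionCohort,
    adjust_pvalues,
    cox_screen,
    fisher_enrichment_one_sided,
    log2_fold_change,
    logrank,
    paired_differential,
    unpaired_differential,
    zscore_normalize,
)

from conftest import make_cohort
from oracles import fisher_one_sided_by_enumeration, rank_sum_exact_p, signed_rank_exact_p


# ----------------------------------------------------------------- fold change


class TestLog2FoldChange:
    def test_identical_means(self):
        assert log2_fold_change([1, 2, 3], [3, 2, 1]) == 0

    def test_arithmetic(self):
        assert log2_fold_change([3, 3], [1, 1]) == 2

    def test_matches_direct_recomputation(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(7)
        assert log2_fold_change(a, b) == pytest.approx(a.mean() - b.mean(), abs=1e-14)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            log2_fold_change([], [1])


# ----------------------------------------------------------------- adjustments


class TestAdjustPvalues:
    def test_single_p_unchanged_bh(self):
        assert adjust_pvalues([0.03], "BH")[0] == pytest.approx(0.03)

    def test_bh_step_up_hand_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "BH")
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni(self):
        assert adjust_pvalues([0.4, 0.6], "bonferroni") == pytest.approx([0.8, 1.0])

    def test_bh_never_decreases_and_capped(self, rng):
        p = rng.random(50)
        out = adjust_pvalues(p, "BH")
        assert (out >= p - 1e-15).all() and (out <= 1).all()

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(30)
        ours = adjust_pvalues(p, "BH")
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "BH")


# ----------------------------------------------------------------- paired test


def paired_cohort(diff_matrix):
    """Build a paired cohort where tumor - normal equals diff_matrix."""
    n_genes, n_pairs = diff_matrix.shape
    genes = [f"g{i}" for i in range(n_genes)]
    tumors = [f"t{i}" for i in range(n_pairs)]
    normals = [f"n{i}" for i in range(n_pairs)]
    rng = np.random.default_rng(0)
    base = rng.standard_normal((n_genes, n_pairs))
    expr = pd.DataFrame(
        np.hstack([base + diff_matrix, base]), index=genes, columns=tumors + normals
    )
    clin = pd.DataFrame(
        {
            "group": ["tumor"] * n_pairs + ["normal"] * n_pairs,
            "pair_id": [f"p{i}" for i in range(n_pairs)] * 2,
        },
        index=pd.Index(tumors + normals, name="sample_id"),
    )
    return ExpressionCohort(expr, clin)


class TestPairedDifferential:
    def test_identical_pairs_p1(self):
        diffs = np.zeros((2, 6))
        diffs[1] = [1, -1, 2, -2, 0.5, -0.5]
        cohort = paired_cohort(diffs)
        res = paired_differential(cohort, "tumor", "normal")
        assert res.loc["g0", "p"] == 1.0
        assert res.loc["g0", "log2FC"] == pytest.approx(0.0, abs=1e-12)

    def test_six_positive_pairs_exact_tail(self):
        diffs = np.array([[0.3, 0.9, 1.4, 2.2, 0.7, 1.1]])
        diffs = np.vstack([diffs, np.random.default_rng(1).standard_normal((1, 6))])
        cohort = paired_cohort(diffs)
        res = paired_differential(cohort, "tumor", "normal")
        assert res.loc["g0", "p"] == pytest.approx(2 / 64, abs=1e-12)

    def test_matches_sign_enumeration_oracle(self, rng):
        diffs = rng.standard_normal((10, 8))
        cohort = paired_cohort(diffs)
        res = paired_differential(cohort, "tumor", "normal")
        for i in range(10):
            assert res.iloc[i]["p"] == pytest.approx(
                signed_rank_exact_p(diffs[i]), abs=1e-10
            )

    def test_too_few_pairs(self):
        cohort = paired_cohort(np.ones((2, 2)))
        with pytest.raises(ValueError):
            paired_differential(cohort, "tumor", "normal")


class TestUnpairedDifferential:
    def test_identical_multisets_p1(self):
        genes = ["g0", "g1"]
        vals = np.array([[1.0, 2, 3, 4, 1, 2, 3, 4], [5, 1, 2, 8, 2, 8, 5, 1]])
        expr = pd.DataFrame(vals, index=genes, columns=[f"s{i}" for i in range(8)])
        clin = pd.DataFrame(
            {"group": ["A"] * 4 + ["B"] * 4}, index=pd.Index(expr.columns)
        )
        res = unpaired_differential(ExpressionCohort(expr, clin), "A", "B")
        assert res.loc["g0", "p"] == pytest.approx(1.0)

    def test_complete_separation_exact_tail(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4, 10, 11, 12, 13]],
            index=["g0"],
            columns=[f"s{i}" for i in range(8)],
        )
        clin = pd.DataFrame({"group": ["B"] * 4 + ["A"] * 4}, index=expr.columns)
        res = unpaired_differential(ExpressionCohort(expr, clin), "A", "B")
        assert res.loc["g0", "p"] == pytest.approx(2 / 70, abs=1e-12)

    def test_matches_exhaustive_labelings(self, rng):
        for _ in range(10):
            a = rng.standard_normal(4)
            b = rng.standard_normal(4)
            expr = pd.DataFrame(
                [np.concatenate([a, b])], index=["g"], columns=[f"s{i}" for i in range(8)]
            )
            clin = pd.DataFrame({"group": ["A"] * 4 + ["B"] * 4}, index=expr.columns)
            res = unpaired_differential(ExpressionCohort(expr, clin), "A", "B")
            assert res.loc["g", "p"] == pytest.approx(rank_sum_exact_p(a, b), abs=1e-10)

    def test_missing_group_raises(self, rng):
        cohort = make_cohort(rng)
        with pytest.raises(ValueError):
            unpaired_differential(cohort, "A", "Z")


# ------------------------------------------------------------------ cox screen


def survival_cohort(rng, n=300, beta=0.0, n_genes=1, censor_frac=0.3):
    genes = [f"g{i}" for i in range(n_genes)]
    x = rng.standard_normal((n_genes, n))
    hazard = 0.001 * np.exp(beta * x[0])
    t_event = rng.exponential(1.0 / hazard)
    c = rng.exponential(t_event.mean() / max(censor_frac, 1e-9) * 0.4, size=n)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    samples = [f"s{i}" for i in range(n)]
    expr = pd.DataFrame(x, index=genes, columns=samples)
    clin = pd.DataFrame(
        {"time": np.maximum(time, 1e-3), "event": event}, index=pd.Index(samples)
    )
    return ExpressionCohort(expr, clin)


class TestCoxScreen:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        cohort = survival_cohort(rng, n=500, beta=0.0, n_genes=200)
        res = cox_screen(cohort)
        ok = res[res["status"] == "ok"]
        assert len(ok) >= 190
        ks = sps.kstest(ok["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_hazard_detected(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            cohort = survival_cohort(rng, n=300, beta=np.log(2.0))
            res = cox_screen(cohort)
            rec = res.iloc[0]
            if rec["coefficient"] > 0 and rec["p"] < 0.01:
                hits += 1
        assert hits >= 16  # >= 80%

    def test_constant_gene_flagged(self, rng):
        cohort = survival_cohort(rng, n=100, n_genes=2)
        cohort.expression.loc["g1"] = 0.0
        cohort.expression.iloc[1, 0] = 0.0  # keep variance zero after construction
        expr = cohort.expression.copy()
        expr.loc["g1"] = 1.0
        expr.loc["g1", expr.columns[0]] = 1.0
        flat = ExpressionCohort.__new__(ExpressionCohort)
        flat.expression = expr
        flat.clinical = cohort.clinical
        res = cox_screen(flat)
        assert res.loc["g1", "status"] == "non_informative"

    def test_hazard_ratio_is_exp_coefficient(self, rng):
        cohort = survival_cohort(rng, n=150, beta=0.5, n_genes=3)
        res = cox_screen(cohort)
        ok = res[res["status"] == "ok"]
        assert np.allclose(ok["hazard_ratio"], np.exp(ok["coefficient"]))


# --------------------------------------------------------------------- logrank


class TestLogrank:
    def _cohort(self, rng, n=200, hr=1.0):
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        hazard = np.where(labels == "A", 0.002 * hr, 0.002)
        t = rng.exponential(1.0 / hazard)
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(
            rng.standard_normal((2, n)), index=["g0", "g1"], columns=samples
        )
        clin = pd.DataFrame({"time": t, "event": 1}, index=pd.Index(samples))
        return ExpressionCohort(expr, clin), pd.Series(labels, index=samples)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(60):
            cohort, labels = self._cohort(rng, n=60, hr=1.0)
            ps.append(logrank(cohort, labels)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_hr3_power(self):
        rng = np.random.default_rng(6)
        hits = sum(
            logrank(*self._cohort(rng, n=200, hr=3.0))[1] < 0.01 for _ in range(20)
        )
        assert hits >= 18

    def test_hand_computed_toy(self):
        # 6 subjects, two groups, all events; statistic recomputed by hand
        # via the standard O-E / V log-rank table:
        # times 1..6, group A = {1, 3, 5}, B = {2, 4, 6}
        samples = [f"s{i}" for i in range(6)]
        expr = pd.DataFrame([np.zeros(6) + np.arange(6)], index=["g"], columns=samples)
        clin = pd.DataFrame(
            {"time": [1, 2, 3, 4, 5, 6], "event": 1}, index=pd.Index(samples)
        )
        labels = pd.Series(["A", "B", "A", "B", "A", "B"], index=samples)
        stat, p = logrank(ExpressionCohort(expr, clin), labels)
        # hand table: O_A = 3; E_A = 6/6+4/5+3/4+2/3+1/2 (A at risk counts)
        # E_A = 1/2 + 2/5 + 1/2 + 1/3 + 1/2 + 0 -> computed below
        e_a, v = 0.0, 0.0
        at_risk = [("A", 1), ("B", 2), ("A", 3), ("B", 4), ("A", 5), ("B", 6)]
        for i, (g, t) in enumerate(at_risk):
            n_total = 6 - i
            n_a = sum(1 for gg, tt in at_risk[i:] if gg == "A")
            e_a += n_a / n_total
            if n_total > 1:
                v += (n_a / n_total) * (1 - n_a / n_total)
        o_a = 3
        expected_stat = (o_a - e_a) ** 2 / v
        assert stat == pytest.approx(expected_stat, rel=1e-6)

    def test_single_group_raises(self, rng):
        cohort, labels = self._cohort(rng, n=20)
        with pytest.raises(ValueError):
            logrank(cohort, labels.map(lambda _: "A"))


# ---------------------------------------------------------------------- fisher


class TestFisher:
    def test_closed_form(self):
        assert fisher_enrichment_one_sided([[5, 0], [0, 5]]) == pytest.approx(1 / 252)

    def test_flat_table(self):
        assert fisher_enrichment_one_sided([[1, 1], [1, 1]]) > 0.5

    def test_matches_enumeration(self, rng):
        for _ in range(25):
            t = rng.integers(0, 7, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_enrichment_one_sided(t) == pytest.approx(
                fisher_one_sided_by_enumeration(t.tolist()), abs=1e-12
            )

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            fisher_enrichment_one_sided([[1, -1], [0, 2]])


# --------------------------------------------------------------------- zscore


class TestZscore:
    def test_hand_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = zscore_normalize(m)
        assert out.loc["g"].tolist() == pytest.approx([-1, 0, 1])

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.standard_normal((5, 20)))
        once = zscore_normalize(m)
        twice = zscore_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_row_means_zero(self, rng):
        out = zscore_normalize(pd.DataFrame(rng.standard_normal((30, 15))))
        assert np.abs(out.mean(axis=1)).max() < 1e-10
        assert np.allclose(out.std(axis=1, ddof=1), 1.0)

    def test_zero_sd_row_named(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0]], index=["flatgene"], columns=list("abc"))
        with pytest.raises(ValueError, match="flatgene"):
            zscore_normalize(m)


# ------------------------------------------------------------------- cohort QC


class TestExpressionCohort:
    def test_zero_variance_genes_dropped(self, rng):
        expr = pd.DataFrame(
            np.vstack([rng.standard_normal((3, 10)), np.ones((1, 10))]),
            index=["a", "b", "c", "flat"],
            columns=[f"s{i}" for i in range(10)],
        )
        cohort = ExpressionCohort(expr)
        assert "flat" not in cohort.genes

    def test_duplicate_samples_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 2)), index=["a", "b"], columns=["s", "s"])
        with pytest.raises(ValueError):
            ExpressionCohort(expr)

    def test_type_i_error_null_simulation(self):
        # unpaired test at alpha=0.05 under the null over 2000 replicates
        rng = np.random.default_rng(11)
        n_rep = 2000
        rejections = 0
        for _ in range(n_rep):
            a, b = rng.standard_normal(6), rng.standard_normal(6)
            p = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            rejections += p <= 0.05
        # MW exact at n=6,6 is conservative; allow MC margin
        assert rejections / n_rep <= 0.05 + 0.02
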