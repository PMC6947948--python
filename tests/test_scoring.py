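import numpy as np
import pytest
from scipy import stats

from iimat import (
    SimulationConfig,
    Triplet,
    combine_ranks,
    gene_pvalue,
    null_scenario,
    pair_pcc,
    permutation_pvalues,
    rank_concordance,
    score_triplets,
    select_dysregulated,
    simulate_scenario,
)
from iimat.types import GeneRoleCatalog, TripletScoreRecord

from conftest import make_expression


TRIPLET = Triplet("G0", "G1", "G2")
CATALOG = GeneRoleCatalog({"G0": {"IMMUNE"}, "G1": {"INFLAMMATION"},
                           "G2": {"DISEASE"}})


class TestGenePvalue:
    def test_identical_groups_give_p_one(self):
        expr = make_expression([[1, 2, 3, 1, 2, 3]], n_case=3)
        assert gene_pvalue(expr, "G0") == 1.0

    def test_pooled_t_closed_form(self):
        # case (1,2,3) vs control (4,5,6): pooled variance 1, t = -3/sqrt(2/3)
        expr = make_expression([[1, 2, 3, 4, 5, 6]], n_case=3)
        t = -3.0 / np.sqrt(2.0 / 3.0)
        expected = 2 * stats.t.sf(abs(t), 4)
        p = gene_pvalue(expr, "G0")
        assert p == pytest.approx(expected)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_constant_equal_groups(self):
        expr = make_expression([[5, 5, 5, 5, 5]], n_case=2)
        assert gene_pvalue(expr, "G0") == 1.0

    def test_constant_unequal_groups_floor(self):
        expr = make_expression([[5, 5, 7, 7]], n_case=2)
        assert gene_pvalue(expr, "G0") == 1e-300

    def test_absent_gene_errors(self):
        expr = make_expression([[1, 2, 3, 4]], n_case=2)
        with pytest.raises(KeyError):
            gene_pvalue(expr, "NOPE")

    def test_matches_scipy_student_and_welch(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 13))
        expr = make_expression(x, n_case=6)
        a, b = x[0, :6], x[0, 6:]
        assert gene_pvalue(expr, "G0") == pytest.approx(
            stats.ttest_ind(a, b).pvalue)
        assert gene_pvalue(expr, "G0", test="welch") == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue)


class TestPairPCC:
    def test_perfect_correlation(self):
        expr = make_expression([[1, 2, 3, 0, 0, 1], [1, 2, 3, 1, 0, 0]],
                               n_case=3)
        assert pair_pcc(expr, "G0", "G1", "CASE") == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        expr = make_expression([[1, 2, 3, 0, 0, 1], [3, 2, 1, 1, 0, 0]],
                               n_case=3)
        assert pair_pcc(expr, "G0", "G1", "CASE") == pytest.approx(-1.0)

    def test_textbook_covariance_formula(self):
        x, y = np.array([1, 2, 4.0]), np.array([1, 3, 3.0])
        expr = make_expression(np.array([
            np.concatenate([x, [0, 0, 1]]),
            np.concatenate([y, [1, 0, 0]]),
        ]), n_case=3)
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean())**2)
                              * np.sum((y - y.mean())**2)))
        assert pair_pcc(expr, "G0", "G1", "CASE") == pytest.approx(r_oracle)

    def test_constant_vector_gives_zero(self):
        expr = make_expression([[7, 7, 7, 0, 0, 1], [1, 2, 3, 1, 0, 0]],
                               n_case=3)
        assert pair_pcc(expr, "G0", "G1", "CASE") == 0.0

    def test_too_few_samples_error(self):
        expr = make_expression([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]],
                               n_case=2)
        with pytest.raises(ValueError, match="need >=3"):
            pair_pcc(expr, "G0", "G1", "CASE")


class TestScoreTriplets:
    def test_identical_groups_give_score_dif_one_and_pcc_zero(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(3, 5))
        expr = make_expression(np.hstack([half, half]), n_case=5)
        (rec,) = score_triplets(expr, [TRIPLET])
        assert rec.score_dif == 1.0
        assert rec.score_pcc == pytest.approx(0.0)

    def test_scores_in_bounds_on_random_data(self):
        rng = np.random.default_rng(5)
        expr = make_expression(rng.normal(size=(3, 16)), n_case=8)
        (rec,) = score_triplets(expr, [TRIPLET])
        assert 0 < rec.score_dif <= 1
        assert 0 <= rec.score_pcc <= 8

    def test_incomplete_gene_drops_triplet(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 10))
        X[3, 2] = np.nan
        expr = make_expression(X, n_case=5)
        other = Triplet("G0", "G1", "G3")
        records = score_triplets(expr, [TRIPLET, other])
        assert [r.triplet for r in records] == [TRIPLET]


class TestCombineRanks:
    def _records(self, score_dif, score_pcc):
        out = []
        for i, (d, p) in enumerate(zip(score_dif, score_pcc)):
            r = TripletScoreRecord(Triplet(f"A{i}", f"B{i}", f"C{i}"))
            r.score_dif, r.score_pcc = d, p
            out.append(r)
        return out

    def test_single_record(self):
        (r,) = combine_ranks(self._records([0.1], [0.5]))
        assert r.rank_dif == r.rank_pcc == r.final_score == 1.0

    def test_hand_ranked_example(self):
        recs = combine_ranks(self._records([0.001, 0.5, 0.9], [2.0, 0.1, 0.5]))
        assert [r.rank_dif for r in recs] == [3, 2, 1]
        assert [r.rank_pcc for r in recs] == [3, 1, 2]
        assert [r.final_score for r in recs] == [3.0, 1.5, 1.5]

    def test_all_tied(self):
        recs = combine_ranks(self._records([0.5] * 4, [0.2] * 4))
        assert len({r.final_score for r in recs}) == 1

    def test_input_order_invariance(self):
        dif, pcc = [0.3, 0.01, 0.8, 0.2], [1.0, 0.4, 0.0, 2.2]
        fwd = combine_ranks(self._records(dif, pcc))
        rev = combine_ranks(self._records(dif[::-1], pcc[::-1]))
        assert [r.final_score for r in fwd] == [r.final_score for r in rev][::-1]

    def test_monotone_in_score_dif(self):
        # decreasing one record's score_dif (no ties) never decreases its
        # final score
        dif, pcc = [0.3, 0.05, 0.8], [1.0, 0.4, 0.2]
        before = combine_ranks(self._records(dif, pcc))[0].final_score
        dif2 = [0.01, 0.05, 0.8]
        after = combine_ranks(self._records(dif2, pcc))[0].final_score
        assert after >= before


class TestPermutation:
    def test_nperm_zero_is_an_error(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.normal(size=(3, 12)), n_case=6)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_pvalues(expr, [TRIPLET], n_perm=0, seed=1)

    def test_add_one_convention_and_reproducibility(self):
        rng = np.random.default_rng(2)
        expr = make_expression(rng.normal(size=(6, 14)), n_case=7)
        trs = [TRIPLET, Triplet("G3", "G4", "G5")]
        a = permutation_pvalues(expr, trs, n_perm=49, seed=11)
        b = permutation_pvalues(expr, trs, n_perm=49, seed=11)
        for ra, rb in zip(a, b):
            assert ra.perm_p == rb.perm_p
            # perm_p is always (1 + c) / (1 + n_perm) for integer c
            count = ra.perm_p * 50 - 1
            assert count == pytest.approx(round(count))
            assert 1 / 50 <= ra.perm_p <= 1.0

    def test_label_swap_leaves_scores_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 12))
        expr = make_expression(X, n_case=5)
        swapped = make_expression(X, labels={
            s: ("CONTROL" if g == "CASE" else "CASE")
            for s, g in expr.labels.items()
        })
        (r1,) = score_triplets(expr, [TRIPLET])
        (r2,) = score_triplets(swapped, [TRIPLET])
        assert r1.score_dif == pytest.approx(r2.score_dif)
        assert r1.score_pcc == pytest.approx(r2.score_pcc)

    def test_null_pvalues_roughly_uniform(self):
        scenario = null_scenario(SimulationConfig(seed=5), n_triangles_null=60,
                                 n_genes=200)
        recs = permutation_pvalues(scenario.expression,
                                   list(scenario.truth.null),
                                   n_perm=100, seed=5)
        ps = np.array([r.perm_p for r in recs])
        assert 0.3 < ps.mean() < 0.7
        # fraction below 0.05 within a generous binomial band around 5%
        assert (ps < 0.05).mean() <= stats.binom.ppf(0.999, 60, 0.05) / 60

    def test_planted_signal_detected(self):
        scenario = simulate_scenario(SimulationConfig(
            seed=9, n_triangles_planted=5, n_triangles_null=45, n_genes=200))
        trs = list(scenario.truth.planted) + list(scenario.truth.null)
        recs = permutation_pvalues(scenario.expression, trs, n_perm=100,
                                   seed=9)
        by_triplet = {r.triplet: r for r in recs}
        planted = [by_triplet[t] for t in scenario.truth.planted]
        assert all(r.perm_p < 0.05 for r in planted)
        order = sorted(recs, key=lambda r: -r.final_score)
        assert {r.triplet for r in order[:5]} == set(scenario.truth.planted)

    def test_cohort_reference_caps_significance(self):
        # joint re-ranking makes permuted finals marginally uniform, so null
        # p-values stay calibrated there too
        scenario = null_scenario(SimulationConfig(seed=6),
                                 n_triangles_null=40, n_genes=150)
        recs = permutation_pvalues(scenario.expression,
                                   list(scenario.truth.null), n_perm=100,
                                   seed=6, null_reference="cohort")
        ps = np.array([r.perm_p for r in recs])
        assert 0.3 < ps.mean() < 0.7


class TestSelection:
    def _scored(self, perm_ps):
        out = []
        for i, p in enumerate(perm_ps):
            r = TripletScoreRecord(Triplet(f"A{i}", f"B{i}", f"C{i}"))
            r.perm_p = p
            r.final_score = len(perm_ps) - i
            out.append(r)
        return out

    @property
    def _catalog(self):
        entries = {}
        for i in range(10):
            entries[f"A{i}"] = {"IMMUNE"}
            entries[f"B{i}"] = {"INFLAMMATION"}
            entries[f"C{i}"] = {"DISEASE"}
        return GeneRoleCatalog(entries)

    def test_all_insignificant_gives_empty_network(self):
        net = select_dysregulated(self._scored([1.0, 1.0]), self._catalog)
        assert net.records == [] and net.edges == set()

    def test_single_hit_builds_triangle(self):
        net = select_dysregulated(self._scored([0.01, 0.9]), self._catalog)
        assert len(net.records) == 1
        assert len(net.nodes) == 3 and len(net.edges) == 3

    def test_alpha_boundary_is_strict(self):
        net = select_dysregulated(self._scored([0.04, 0.05, 0.06]),
                                  self._catalog, alpha=0.05)
        assert len(net.records) == 1


class TestRankConcordance:
    def _records(self, finals):
        out = []
        for i, f in enumerate(finals):
            r = TripletScoreRecord(Triplet(f"A{i}", f"B{i}", f"C{i}"))
            r.final_score = f
            out.append(r)
        return out

    def test_top_k_selection_is_100(self):
        recs = self._records([10, 9, 8, 7, 6, 5])
        assert rank_concordance(recs, recs[:3]) == 100.0

    def test_partial_overlap(self):
        recs = self._records(range(10, 0, -1))
        selected = [recs[0], recs[1], recs[2], recs[7]]  # 3 of 4 in top 4
        assert rank_concordance(recs, selected) == 75.0

    def test_single_top_record(self):
        recs = self._records([5, 4])
        assert rank_concordance(recs, recs[:1]) == 100.0

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            rank_concordance(self._records([1.0]), [])
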