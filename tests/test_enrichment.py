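"""Ranking, weighted-KS pathway scores, permutation null, p-values, FDR."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dyspia import (
    BackgroundSet,
    DysGpsTable,
    GenePair,
    PathwayPairSet,
    PhenotypeLabels,
    RankedPairList,
    ValidationError,
    all_enrichment_scores,
    bh_fdr,
    build_pathway_index,
    classify_direction,
    enrichment_score,
    nominal_pvalue,
    permutation_null,
    rank_pairs,
    run_dyspia,
)
from dyspia.enrichment import _fast_scores_for_ranking
from tests.conftest import make_expression


def make_table(scores, names=None):
    names = names or [f"A{i:03d}|B{i:03d}" for i in range(len(scores))]
    pairs = [GenePair(*n.split("|")) for n in names]
    return DysGpsTable(pairs=pairs, scores=np.asarray(scores, float), n_case=5, n_control=5)


def naive_running_extrema(scores_desc, positions, p_exp):
    """Independent O(N * |P|) oracle: walk the running sum position by position."""
    N = len(scores_desc)
    hits = set(int(p) for p in positions)
    n_r = sum(abs(scores_desc[p - 1]) ** p_exp for p in hits)
    n_miss = N - len(hits)
    running = 0.0
    s_max = -np.inf
    s_min = np.inf
    for i in range(1, N + 1):
        if i in hits:
            running += abs(scores_desc[i - 1]) ** p_exp / n_r
        else:
            running -= 1.0 / n_miss
        s_max = max(s_max, running)
        s_min = min(s_min, running)
    return s_max, s_min


def naive_running_sum_score(scores_desc, positions, p_exp):
    s_max, s_min = naive_running_extrema(scores_desc, positions, p_exp)
    return s_max if abs(s_max) >= abs(s_min) else s_min


def assert_matches_naive(got, scores_desc, positions, p_exp, tol=1e-12):
    """Magnitudes must agree; signs too, unless the extrema tie in magnitude
    (then float accumulation order may legitimately pick either side)."""
    s_max, s_min = naive_running_extrema(scores_desc, positions, p_exp)
    expected = s_max if abs(s_max) >= abs(s_min) else s_min
    if abs(abs(s_max) - abs(s_min)) > 1e-9:
        assert abs(got - expected) < tol
    else:
        assert min(abs(got - s_max), abs(got - s_min)) < tol


class TestRankPairs:
    def test_descending_order(self):
        table = make_table([1.0, 3.0, -2.0], ["a|x", "b|x", "c|x"])
        ranked = rank_pairs(table)
        assert [p.gene_a for p in ranked.pairs] == ["b", "a", "c"]
        assert ranked.scores.tolist() == [3.0, 1.0, -2.0]

    def test_ties_broken_by_name(self):
        table = make_table([1.0, 1.0, 1.0], ["z|zz", "a|aa", "m|mm"])
        ranked = rank_pairs(table)
        assert [p.label for p in ranked.pairs] == ["a|aa", "m|mm", "z|zz"]

    def test_nan_rejected(self):
        with pytest.raises(ValidationError, match="NaN"):
            rank_pairs(make_table([1.0, np.nan]))

    def test_matches_reference_sort(self, rng):
        scores = rng.standard_normal(10_000)
        table = make_table(scores)
        ranked = rank_pairs(table)
        reference = sorted(
            zip(scores, (p.label for p in table.pairs)), key=lambda t: (-t[0], t[1])
        )
        assert ranked.scores.tolist() == [s for s, _ in reference]
        assert [p.label for p in ranked.pairs] == [l for _, l in reference]


class TestEnrichmentScore:
    def test_single_pair_at_top(self, rng):
        ranked = RankedPairList(
            pairs=[GenePair(f"a{i:03d}", f"b{i:03d}") for i in range(100)],
            scores=np.sort(rng.standard_normal(100))[::-1],
        )
        assert enrichment_score(ranked, np.array([1])) == pytest.approx(1.0)

    def test_single_pair_at_bottom(self, rng):
        scores = np.sort(rng.standard_normal(100))[::-1]
        ranked = RankedPairList(
            pairs=[GenePair(f"a{i:03d}", f"b{i:03d}") for i in range(100)],
            scores=scores,
        )
        assert enrichment_score(ranked, np.array([100])) == pytest.approx(-1.0)

    def test_toy_list_matches_naive_oracle(self, rng):
        scores = np.sort(rng.standard_normal(50))[::-1]
        positions = np.sort(rng.choice(np.arange(1, 51), size=5, replace=False))
        got = enrichment_score(scores, positions, p_exp=1.0)
        assert got == pytest.approx(
            naive_running_sum_score(scores, positions, 1.0), abs=1e-12
        )

    def test_unweighted_equals_classic_ks(self, rng):
        # p = 0 reduces to the two-sample KS statistic on hit vs miss ranks
        for _ in range(20):
            N = int(rng.integers(20, 200))
            m = int(rng.integers(1, N // 2))
            scores = np.sort(rng.standard_normal(N))[::-1]
            pos = np.sort(rng.choice(np.arange(1, N + 1), size=m, replace=False))
            got = enrichment_score(scores, pos, p_exp=0.0)
            miss = np.setdiff1d(np.arange(1, N + 1), pos)
            ks = scipy.stats.ks_2samp(pos, miss, method="asymp").statistic
            assert abs(got) == pytest.approx(ks, abs=1e-12)

    def test_zero_weight_pathway_rejected(self):
        scores = np.array([1.0, 0.0, -1.0])
        with pytest.raises(ValidationError, match="zero"):
            enrichment_score(scores, np.array([2]), p_exp=1.0)


class TestFastScorer:
    @pytest.mark.parametrize("p_exp", [0.0, 1.0, 1.5])
    def test_matches_naive_on_random_instances(self, p_exp, rng):
        for _ in range(200):
            N = int(rng.integers(10, 120))
            m = int(rng.integers(1, N))
            scores = np.sort(rng.standard_normal(N))[::-1]
            pos = np.sort(rng.choice(np.arange(1, N + 1), size=m, replace=False))
            fast = _fast_scores_for_ranking(np.abs(scores) ** p_exp, [pos], N)[0]
            assert_matches_naive(fast, scores, pos, p_exp)

    def test_pathway_covering_all_but_one(self, rng):
        N = 30
        scores = np.sort(rng.standard_normal(N))[::-1]
        pos = np.arange(1, N)  # all but the last pair
        fast = _fast_scores_for_ranking(np.abs(scores), [pos], N)[0]
        assert fast == pytest.approx(naive_running_sum_score(scores, pos, 1.0), abs=1e-12)

    def test_consistent_with_public_api(self, small_dataset, toy_pathways):
        from dyspia import compute_dysgps

        expr, labels, bg = small_dataset
        ranked = rank_pairs(compute_dysgps(expr, labels, bg))
        index = build_pathway_index(ranked, toy_pathways, min_size=1)
        fast = all_enrichment_scores(ranked, index)
        for k, pos in enumerate(index.positions):
            assert fast[k] == pytest.approx(enrichment_score(ranked, pos), abs=1e-12)


class TestNominalPvalue:
    def test_counting(self):
        assert nominal_pvalue(0.9, np.array([0.1, 0.2, 0.3])) == pytest.approx(0.25)

    def test_boundary_value_counted(self):
        null = np.array([0.1, 0.5, 0.3])
        assert nominal_pvalue(0.5, null) == pytest.approx(2 / 4)

    def test_empty_portion_gives_one(self):
        assert nominal_pvalue(-0.5, np.array([0.1, 0.2])) == 1.0

    def test_negative_branch_mirrors(self):
        null = np.array([-0.1, -0.2, -0.3, 0.4])
        assert nominal_pvalue(-0.25, null) == pytest.approx((1 + 1) / (1 + 3))

    def test_monotone_in_magnitude(self, rng):
        null = rng.standard_normal(500)
        obs = np.linspace(0, 3, 40)
        ps = [nominal_pvalue(o, null) for o in obs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(10):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 60)))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(1e-6, 1.0, size=50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "dysps, fdr, expected",
        [(0.7, 0.01, "gain"), (-0.7, 0.01, "loss"), (0.7, 0.06, "not_significant")],
    )
    def test_calls(self, dysps, fdr, expected):
        assert classify_direction(dysps, fdr, alpha=0.05) == expected


class TestPermutationNull:
    def test_exhaustive_mode_for_tiny_samples(self, rng):
        with pytest.warns(UserWarning):
            expr, labels = make_expression(12, 2, 3, rng)
        pairs = [
            GenePair(*sorted((expr.gene_ids[i], expr.gene_ids[j])))
            for i in range(6)
            for j in range(6, 12)
        ]
        bg = BackgroundSet(pairs=pairs, provenance=["observed"] * len(pairs))
        pw = PathwayPairSet("pw", "pw", frozenset(pairs[:8]))
        null = permutation_null(expr, labels, bg, [pw], n_perm=1000, seed=0, min_size=1)
        assert null.exhaustive
        assert null.values.shape == (10, 1)  # C(5, 2) distinct label splits

    def test_deterministic_given_seed(self, small_dataset, toy_pathways):
        expr, labels, bg = small_dataset
        a = permutation_null(expr, labels, bg, toy_pathways, n_perm=25, seed=3, min_size=1)
        b = permutation_null(expr, labels, bg, toy_pathways, n_perm=25, seed=3, min_size=1)
        np.testing.assert_array_equal(a.values, b.values)
        c = permutation_null(expr, labels, bg, toy_pathways, n_perm=25, seed=4, min_size=1)
        assert not np.array_equal(a.values, c.values)


class TestRunDyspia:
    def test_end_to_end_deterministic(self, small_dataset, toy_pathways, tmp_path):
        from dyspia import io

        expr, labels, bg = small_dataset
        kwargs = dict(bg=bg, n_perm=50, seed=1, min_size=1)
        r1 = run_dyspia(expr, labels, toy_pathways, **kwargs)
        r2 = run_dyspia(expr, labels, toy_pathways, **kwargs)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        io.write_results(r1, p1)
        io.write_results(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_label_swap_flips_scores_keeps_pvalues(self, small_dataset, toy_pathways):
        expr, labels, bg = small_dataset
        fwd = run_dyspia(expr, labels, toy_pathways, bg=bg, n_perm=40, seed=2, min_size=1)
        rev = run_dyspia(
            expr, labels.swapped(), toy_pathways, bg=bg, n_perm=40, seed=2, min_size=1
        )
        fwd_by_id = {r.pathway_id: r for r in fwd}
        for r in rev:
            assert r.dysps == pytest.approx(-fwd_by_id[r.pathway_id].dysps, abs=1e-12)

    def test_size_filter_fatal_when_nothing_passes(self, small_dataset, toy_pathways):
        expr, labels, bg = small_dataset
        with pytest.raises(Exception, match="size filter"):
            run_dyspia(expr, labels, toy_pathways, bg=bg, n_perm=10, seed=0, min_size=1000)

    def test_exhaustive_pvalues_on_achievable_grid(self, rng):
        # with K exhaustive splits, p must equal (1 + b) / (1 + m) for integer
        # b <= m <= K
        with pytest.warns(UserWarning):
            expr, labels = make_expression(10, 2, 3, rng)
        pairs = [
            GenePair(*sorted((expr.gene_ids[i], expr.gene_ids[j])))
            for i in range(5)
            for j in range(5, 10)
        ]
        bg = BackgroundSet(pairs=pairs, provenance=["observed"] * len(pairs))
        pws = [
            PathwayPairSet(
                f"pw{k}", f"pw{k}",
                frozenset(pairs[i] for i in rng.choice(len(pairs), 6, replace=False)),
            )
            for k in range(4)
        ]
        results = run_dyspia(expr, labels, pws, bg=bg, n_perm=1000, seed=0, min_size=1)
        achievable = {
            (1 + b) / (1 + m) for m in range(11) for b in range(m + 1)
        }
        for r in results:
            assert any(abs(r.pval - a) < 1e-12 for a in achievable)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_fast_and_naive_scorers_agree_property(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(5, 80))
    m = int(rng.integers(1, N))
    scores = np.sort(rng.standard_normal(N))[::-1]
    pos = np.sort(rng.choice(np.arange(1, N + 1), size=m, replace=False))
    fast = _fast_scores_for_ranking(np.abs(scores), [pos], N)[0]
    assert_matches_naive(fast, scores, pos, 1.0)
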