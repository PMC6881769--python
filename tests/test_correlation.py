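import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kmersig.correlation import (
    Comparison,
    CorrelationMatrix,
    cc_matrix,
    group_summaries,
    pair_count,
    pairwise_cc,
    read_cc_matrix,
    welch_cohen,
    write_cc_matrix,
)
from kmersig.scoring import KmerSignature, build_signature
from kmersig.sequence_io import CompositionProfile

UNIFORM = CompositionProfile(0.25, 0.25, 0.25, 0.25)


def sig_from_scores(species_id, kmers, scores, k=None):
    """Minimal signature carrying just k-mer scores."""
    k = k or len(kmers[0])
    order = np.argsort(kmers)
    return KmerSignature(
        species_id=species_id,
        k=k,
        region_label="whole_genome",
        l_used=0,
        composition=UNIFORM,
        kmers=np.asarray(kmers, dtype=f"U{k}")[order],
        scores=np.asarray(scores, dtype=float)[order],
    )


def hand_pearson(xs, ys):
    """Textbook Pearson formula, independent of scipy."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


KMERS4 = ["AAAA", "ACGT", "GGCC", "TTTT"]


class TestPairwiseCC:
    def test_self_correlation_is_one(self, random_records):
        sig = build_signature(random_records([400], seed=1), 3, "x")
        assert pairwise_cc(sig, sig) == pytest.approx(1.0)

    def test_exact_negation_is_minus_one(self):
        a = sig_from_scores("a", KMERS4, [0.1, 0.2, -0.1, 0.4])
        b = sig_from_scores("b", KMERS4, [-0.1, -0.2, 0.1, -0.4])
        assert pairwise_cc(a, b) == pytest.approx(-1.0)

    def test_matches_hand_formula(self):
        xs = [0.1, 0.2, -0.1, 0.4]
        ys = [0.0, 0.3, -0.2, 0.1]
        a = sig_from_scores("a", KMERS4, xs)
        b = sig_from_scores("b", KMERS4, ys)
        assert pairwise_cc(a, b) == pytest.approx(hand_pearson(xs, ys), abs=1e-12)

    def test_private_kmers_are_omitted(self):
        a = sig_from_scores("a", KMERS4, [0.1, 0.2, -0.1, 0.4])
        b = sig_from_scores("b", KMERS4, [0.0, 0.3, -0.2, 0.1])
        base = pairwise_cc(a, b)
        a_extra = sig_from_scores(
            "a", KMERS4 + ["CCCC"], [0.1, 0.2, -0.1, 0.4, 0.99]
        )
        assert pairwise_cc(a_extra, b) == pytest.approx(base, abs=1e-15)

    def test_order_of_shared_kmers_is_irrelevant(self):
        # same data presented in different insertion orders
        a = sig_from_scores("a", KMERS4, [0.1, 0.2, -0.1, 0.4])
        perm = [2, 0, 3, 1]
        b1 = sig_from_scores("b", KMERS4, [0.0, 0.3, -0.2, 0.1])
        b2 = sig_from_scores(
            "b", [KMERS4[i] for i in perm], [[0.0, 0.3, -0.2, 0.1][i] for i in perm]
        )
        assert pairwise_cc(a, b1) == pairwise_cc(a, b2)

    def test_k_mismatch_rejected(self):
        a = sig_from_scores("a", KMERS4, [0.1, 0.2, -0.1, 0.4])
        b = sig_from_scores("b", ["AAA", "CCC", "GGG"], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="k mismatch"):
            pairwise_cc(a, b)

    def test_too_few_shared_kmers_rejected(self):
        a = sig_from_scores("a", ["AAAA", "ACGT"], [0.1, 0.2])
        b = sig_from_scores("b", ["AAAA", "ACGT"], [0.3, 0.1])
        with pytest.raises(ValueError, match="shared"):
            pairwise_cc(a, b)

    def test_zero_variance_rejected(self):
        a = sig_from_scores("a", KMERS4, [0.5, 0.5, 0.5, 0.5])
        b = sig_from_scores("b", KMERS4, [0.0, 0.3, -0.2, 0.1])
        with pytest.raises(ValueError, match="variance"):
            pairwise_cc(a, b)


class TestCCMatrix:
    def test_identical_signatures_give_unit_offdiagonal(self, random_records):
        recs = random_records([300], seed=4)
        a = build_signature(recs, 3, "a")
        b = build_signature(recs, 3, "b")
        m = cc_matrix([a, b])
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_unit_diagonal_and_equivariance(self, random_records):
        sigs = [
            build_signature(random_records([260 + 31 * i], seed=i), 3, f"s{i}")
            for i in range(4)
        ]
        m = cc_matrix(sigs)
        assert np.allclose(m.values, m.values.T)
        assert np.array_equal(np.diag(m.values), np.ones(4))
        perm = [2, 0, 3, 1]
        m2 = cc_matrix([sigs[i] for i in perm])
        idx = [m.species.index(s) for s in m2.species]
        np.testing.assert_allclose(m2.values, m.values[np.ix_(idx, idx)], atol=1e-15)

    def test_duplicate_ids_rejected(self, random_records):
        recs = random_records([300], seed=4)
        sigs = [build_signature(recs, 3, "same"), build_signature(recs, 3, "same")]
        with pytest.raises(ValueError, match="duplicate"):
            cc_matrix(sigs)

    def test_tsv_round_trip(self, tmp_path, random_records):
        sigs = [
            build_signature(random_records([300 + i], seed=i), 3, f"s{i}")
            for i in range(3)
        ]
        m = cc_matrix(sigs)
        path = tmp_path / "cc.tsv"
        write_cc_matrix(m, path)
        back = read_cc_matrix(path)
        assert back.species == m.species
        np.testing.assert_allclose(back.values, m.values, atol=1e-6)


class TestPairCount:
    @pytest.mark.parametrize("n, expect", [(22, 231), (30, 435), (6, 15), (2, 1), (63, 1953)])
    def test_distinct_unordered_pairs(self, n, expect):
        assert pair_count(n) == expect

    def test_rejects_singletons(self):
        with pytest.raises(ValueError):
            pair_count(1)


def synthetic_roster_matrix(seed=0):
    """58-species matrix with genus-sized groups (22/30/6) and random CCs."""
    rng = np.random.default_rng(seed)
    species = (
        [f"ano{i:02d}" for i in range(22)]
        + [f"dro{i:02d}" for i in range(30)]
        + [f"glo{i}" for i in range(6)]
    )
    groups = {s: s[:3] for s in species}
    n = len(species)
    raw = rng.uniform(0.3, 0.99, size=(n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(species, values, k=8), groups


class TestGroupSummaries:
    def test_table_style_comparison_counts(self):
        matrix, groups = synthetic_roster_matrix()
        specs = [
            Comparison("within", "ano"),
            Comparison("within", "dro"),
            Comparison("within", "glo"),
            Comparison("between", "ano", "dro"),
            Comparison("complement", "glo"),
            Comparison("complement", "ano"),
            Comparison("complement", "dro"),
        ]
        counts = [s.n_comparisons for s in group_summaries(matrix, groups, specs)]
        assert counts == [231, 435, 15, 660, 1326, 630, 378]

    def test_constant_group(self):
        species = ["a1", "a2", "a3"]
        values = np.full((3, 3), 0.7)
        np.fill_diagonal(values, 1.0)
        m = CorrelationMatrix(species, values, k=8)
        (s,) = group_summaries(m, {x: "a" for x in species}, [Comparison("within", "a")])
        assert s.min == s.median == s.max == 0.7
        assert s.mean == pytest.approx(0.7, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.n_comparisons == 3

    def test_summary_ordering_invariant(self):
        matrix, groups = synthetic_roster_matrix(seed=5)
        (s,) = group_summaries(matrix, groups, [Comparison("within", "dro")])
        assert s.min <= s.median <= s.max
        assert s.min <= s.mean <= s.max

    def test_unmapped_species_named_in_error(self):
        matrix, groups = synthetic_roster_matrix()
        del groups["dro07"]
        with pytest.raises(ValueError, match="dro07"):
            group_summaries(matrix, groups, [Comparison("within", "ano")])


def hand_welch(xs, ys):
    """Textbook Welch t and Welch-Satterthwaite df, independent of scipy."""
    n1, n2 = len(xs), len(ys)
    m1, m2 = sum(xs) / n1, sum(ys) / n2
    v1 = sum((x - m1) ** 2 for x in xs) / (n1 - 1)
    v2 = sum((y - m2) ** 2 for y in ys) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def hand_cohen_d(xs, ys):
    n1, n2 = len(xs), len(ys)
    m1, m2 = sum(xs) / n1, sum(ys) / n2
    v1 = sum((x - m1) ** 2 for x in xs) / (n1 - 1)
    v2 = sum((y - m2) ** 2 for y in ys) / (n2 - 1)
    pooled = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    return (m1 - m2) / pooled


class TestWelchCohen:
    def test_identical_groups(self):
        res = welch_cohen([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.cohens_d == 0.0
        assert res.d_ci_low <= 0.0 <= res.d_ci_high

    def test_matches_hand_formulas(self):
        xs, ys = [0.95, 0.96, 0.97], [0.70, 0.72, 0.74]
        res = welch_cohen(xs, ys)
        t_hand, _ = hand_welch(xs, ys)
        assert res.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.cohens_d == pytest.approx(hand_cohen_d(xs, ys), rel=1e-12)
        d = res.cohens_d
        var_d = (3 + 3) / 9 + d * d / 12
        assert res.d_ci_high - res.d_ci_low == pytest.approx(
            2 * 1.959963984540054 * math.sqrt(var_d), rel=1e-9
        )
        assert res.d_ci_low <= d <= res.d_ci_high

    def test_duplication_rescales_d_by_known_factor(self):
        # with the sample (n-1) SD, duplicating both groups (n=3 each)
        # multiplies d by sqrt((2n-1)/(2n-2)); under heavy replication the
        # sample SD tends to the population SD of the base lists, so d tends
        # to the population-SD effect size (invariance is asymptotic, and
        # exact only under population SD)
        xs, ys = [0.95, 0.96, 0.97], [0.70, 0.72, 0.74]
        d1 = welch_cohen(xs, ys).cohens_d
        d2 = welch_cohen(xs * 2, ys * 2).cohens_d
        assert d2 == pytest.approx(d1 * math.sqrt(5.0 / 4.0), rel=1e-12)
        v1, v2 = np.var(xs), np.var(ys)  # population variances
        d_pop = (np.mean(xs) - np.mean(ys)) / math.sqrt((v1 + v2) / 2)
        d_big = welch_cohen(xs * 200, ys * 200).cohens_d
        assert d_big == pytest.approx(d_pop, rel=1e-3)

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValueError):
            welch_cohen([1.0], [1.0, 2.0])

    @given(
        xs=st.lists(st.floats(0, 1), min_size=3, max_size=15),
        ys=st.lists(st.floats(0, 1), min_size=3, max_size=15),
    )
    def test_p_value_in_unit_interval(self, xs, ys):
        if np.std(xs) == 0 and np.std(ys) == 0:
            return
        res = welch_cohen(xs, ys)
        assert 0.0 <= res.p_value <= 1.0 or math.isnan(res.p_value)
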