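"""Discretization, mutual information, MaxRel and mRMR rankings.

The mRMR ranking is checked against an independent brute-force greedy oracle
that recomputes relevance and redundancy from scratch with Counter-based
mutual information at every round.
"""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import cnasubtype as cs
from cnasubtype.mrmr import relevance

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def mi_oracle(x, y):
    """Plug-in mutual information in bits, via explicit cell summation."""
    n = len(x)
    cxy = Counter(zip(x, y))
    cx = Counter(x)
    cy = Counter(y)
    return sum(
        (c / n) * math.log2(c * n / (cx[a] * cy[b])) for (a, b), c in cxy.items()
    )


def mrmr_oracle(states, y, top_n):
    """Greedy mRMR recomputing the criterion from scratch each round."""
    p = states.shape[1]
    rel = [mi_oracle(tuple(states[:, j]), tuple(y)) for j in range(p)]
    selected = []
    for _ in range(top_n):
        best, best_score = None, -math.inf
        for j in range(p):
            if j in selected:
                continue
            if selected:
                red = sum(
                    mi_oracle(tuple(states[:, j]), tuple(states[:, s]))
                    for s in selected
                ) / len(selected)
            else:
                red = 0.0
            score = rel[j] - red
            if score > best_score + 1e-12:  # strict improvement: first index wins ties
                best, best_score = j, score
        selected.append(best)
    return selected


def make_matrix(values, labels=("ACA", "ACA", "SCC", "SCC")):
    values = np.asarray(values, dtype=float)
    return cs.CNAMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        probe_ids=[f"p{j}" for j in range(values.shape[1])],
        labels=np.asarray(labels, dtype=object),
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

class TestDiscretize:
    def test_constant_probe_all_zero(self):
        m = make_matrix([[2.0], [2.0], [2.0], [2.0]])
        d = cs.discretize(m)
        assert (d.states == 0).all()

    def test_hand_computed_thresholds(self):
        """(0, 0, 10), alpha=1: mean 3.333, sample sd 5.774 -> (0, 0, +1)."""
        m = make_matrix([[0.0], [0.0], [10.0]], labels=("ACA", "ACA", "SCC"))
        d = cs.discretize(m, alpha=1.0)
        assert d.states[:, 0].tolist() == [0, 0, 1]
        assert d.means[0] == pytest.approx(10 / 3)
        assert d.sds[0] == pytest.approx(np.std([0, 0, 10], ddof=1))

    def test_huge_alpha_collapses_to_zero(self):
        m = make_matrix(np.random.default_rng(0).normal(2, 1, (4, 5)))
        assert (cs.discretize(m, alpha=1e9).states == 0).all()

    def test_states_bounded_to_three_levels(self):
        m = make_matrix(np.random.default_rng(1).normal(2, 1, (4, 6)))
        d = cs.discretize(m)
        assert set(np.unique(d.states)) <= {-1, 0, 1}

    def test_alpha_must_be_positive(self, toy_matrix):
        with pytest.raises(ValueError, match="alpha"):
            cs.discretize(toy_matrix, alpha=0)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        assert cs.mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_independent_vectors_zero_bits(self):
        assert cs.mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_matches_direct_cell_summation(self):
        # joint counts [[2,1],[1,2]] over n=6
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert cs.mutual_information(x, y) == pytest.approx(mi_oracle(tuple(x), tuple(y)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            cs.mutual_information([0, 1], [0, 1, 0])

    @given(
        arrays(np.int8, st.integers(2, 30), elements=st.integers(-1, 1)),
        st.data(),
    )
    def test_symmetry_nonnegativity_self_entropy(self, x, data):
        y = data.draw(
            arrays(np.int8, x.shape[0], elements=st.integers(-1, 1))
        )
        ixy = cs.mutual_information(x, y)
        assert ixy >= 0.0
        assert ixy == pytest.approx(cs.mutual_information(y, x), abs=1e-12)
        # I(x, x) equals the empirical entropy of x
        n = len(x)
        entropy = -sum(
            (c / n) * math.log2(c / n) for c in Counter(x.tolist()).values()
        )
        assert cs.mutual_information(x, x) == pytest.approx(entropy, abs=1e-12)


# ---------------------------------------------------------------------------
# MaxRel
# ---------------------------------------------------------------------------

class TestMaxRel:
    def test_planted_parents_rank_above_nulls(self, small_cohort):
        matrix, truth = small_cohort
        d = cs.discretize(matrix)
        ranked = cs.max_rel_rank(d, matrix, top_n=matrix.n_probes)
        positions = {p: i for i, p in enumerate(ranked.probe_ids)}
        planted = set(truth.all_planted)
        worst_planted = max(positions[p] for p in truth.informative)
        best_null = min(positions[p] for p in matrix.probe_ids if p not in planted)
        assert worst_planted < best_null
        # scores agree with independently computed per-probe MI
        rel = relevance(d, matrix)
        for pid, score in zip(ranked.probe_ids[:10], ranked.scores[:10]):
            j = matrix.probe_ids.index(pid)
            assert score == pytest.approx(
                mi_oracle(tuple(d.states[:, j]), tuple(matrix.y))
            )
            assert score == pytest.approx(rel[j])

    def test_identical_columns_adjacent_in_input_order(self):
        # p0 and p2 identical informative probes, p1 constant (zero relevance);
        # imbalanced classes so the minority sample crosses the sd threshold
        vals = np.array(
            [[3.0, 2.0, 3.0], [3.1, 2.0, 3.1], [3.05, 2.0, 3.05], [1.0, 2.0, 1.0]]
        )
        m = make_matrix(vals, labels=("ACA", "ACA", "ACA", "SCC"))
        ranked = cs.max_rel_rank(cs.discretize(m), m, top_n=3)
        assert ranked.probe_ids == ["p0", "p2", "p1"]
        assert ranked.scores[0] == ranked.scores[1] > ranked.scores[2]

    def test_top_n_truncates(self, small_cohort):
        matrix, _ = small_cohort
        d = cs.discretize(matrix)
        assert len(cs.max_rel_rank(d, matrix, top_n=1)) == 1

    def test_single_class_rejected(self):
        m = make_matrix(np.ones((4, 2)) + np.eye(4, 2), labels=["ACA"] * 4)
        with pytest.raises(ValueError, match="both classes"):
            cs.max_rel_rank(cs.discretize(m), m)


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

class TestMRMR:
    def test_round_one_equals_maxrel_top(self, small_cohort):
        matrix, _ = small_cohort
        d = cs.discretize(matrix)
        assert (
            cs.mrmr_rank(d, matrix, top_n=5).probe_ids[0]
            == cs.max_rel_rank(d, matrix, top_n=1).probe_ids[0]
        )

    @pytest.mark.parametrize("seed,p", [(0, 5), (1, 8), (2, 12), (3, 20)])
    def test_matches_bruteforce_oracle(self, seed, p):
        """Exact ordering agreement with the from-scratch greedy oracle."""
        rng = np.random.default_rng(seed)
        n = 30
        vals = rng.normal(2, 0.5, (n, p))
        vals[:, 0] += np.r_[np.ones(n // 2), np.zeros(n - n // 2)]  # one informative
        vals[:, -1] = vals[:, 0] + rng.normal(0, 0.1, n)  # one redundant copy
        labels = ["ACA"] * (n // 2) + ["SCC"] * (n - n // 2)
        m = make_matrix(vals, labels)
        d = cs.discretize(m)
        ranked = cs.mrmr_rank(d, m, top_n=p)
        expected = mrmr_oracle(d.states, m.y.astype(int), p)
        assert ranked.probe_ids == [f"p{j}" for j in expected]

    def test_no_duplicates_and_contiguous_ranks(self, small_cohort):
        matrix, _ = small_cohort
        ranked = cs.mrmr_rank(cs.discretize(matrix), matrix, top_n=30)
        assert len(set(ranked.probe_ids)) == 30
        assert ranked.ranks.tolist() == list(range(1, 31))

    def test_exact_duplicates_rank_behind_their_parent(self):
        """At equal relevance (exact duplicate columns) the parent is selected
        first and the duplicates are pushed behind independent probes by the
        redundancy penalty, below their MaxRel positions."""
        rng = np.random.default_rng(17)
        n = 40
        base = rng.normal(2, 0.4, (n, 6))
        base[: n - 10, 0] += 1.2  # p0 informative (imbalanced classes)
        base[: n - 10, 3] += 1.0  # p3 weaker independent signal
        vals = np.column_stack([base, base[:, 0], base[:, 0]])  # p6, p7 = copies of p0
        m = make_matrix(vals, ["ACA"] * (n - 10) + ["SCC"] * 10)
        d = cs.discretize(m)
        mr = cs.mrmr_rank(d, m, top_n=8)
        mx = cs.max_rel_rank(d, m, top_n=8)
        mr_pos = {p: i for i, p in enumerate(mr.probe_ids)}
        mx_pos = {p: i for i, p in enumerate(mx.probe_ids)}
        assert mr.probe_ids[0] == "p0"
        for copy in ("p6", "p7"):
            assert mr_pos[copy] > mr_pos["p0"]
            assert mr_pos[copy] > mx_pos[copy]

    def test_jittered_copies_deferred_on_aggregate(self, small_cohort):
        """Jitter perturbs per-copy relevance, but across all redundant copies
        the mRMR ranks sit later than the MaxRel ranks (net deferral)."""
        matrix, truth = small_cohort
        d = cs.discretize(matrix)
        mr = cs.mrmr_rank(d, matrix, top_n=matrix.n_probes)
        mx = cs.max_rel_rank(d, matrix, top_n=matrix.n_probes)
        mr_pos = {p: i for i, p in enumerate(mr.probe_ids)}
        mx_pos = {p: i for i, p in enumerate(mx.probe_ids)}
        copies = [c for cps in truth.partners.values() for c in cps]
        net_deferral = sum(mr_pos[c] - mx_pos[c] for c in copies)
        assert net_deferral > 0

    def test_top_n_exceeding_probe_count_warns_and_truncates(self, toy_matrix):
        with pytest.warns(UserWarning, match="truncating"):
            ranked = cs.mrmr_rank(cs.discretize(toy_matrix), toy_matrix, top_n=99)
        assert len(ranked) == toy_matrix.n_probes

    def test_zero_variance_probe_never_outranks_informative(self):
        vals = np.array([[3.0, 2.0], [3.1, 2.0], [3.05, 2.0], [1.0, 2.0]])
        m = make_matrix(vals, labels=("ACA", "ACA", "ACA", "SCC"))
        ranked = cs.mrmr_rank(cs.discretize(m), m, top_n=2)
        assert ranked.probe_ids[0] == "p0"
        assert ranked.scores[0] > 0

    def test_quotient_combination_runs(self, small_cohort):
        matrix, _ = small_cohort
        d = cs.discretize(matrix)
        rq = cs.mrmr_rank(d, matrix, top_n=10, combination="quotient")
        assert len(rq) == 10


class TestRankingIO:
    def test_round_trip(self, tmp_path, small_cohort):
        matrix, _ = small_cohort
        ranked = cs.mrmr_rank(cs.discretize(matrix), matrix, top_n=10)
        f = tmp_path / "mrmr.tsv"
        cs.mrmr.write_ranking(ranked, f)
        back = cs.mrmr.read_ranking(f)
        assert back.probe_ids == ranked.probe_ids
        assert np.allclose(back.scores, ranked.scores)
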