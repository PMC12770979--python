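import itertools
from math import comb

import numpy as np
import pytest

import motifattn as ma
from motifattn.interpret import (attention_attribution, combine_heads,
                                 dinuc_shuffle, mann_whitney_p,
                                 positions_to_filters, select_candidates)
from motifattn.interpret import test_interactions as run_interaction_tests
from motifattn.nn import Tensor


class TestCombineHeads:
    def test_single_head_identity(self, rng):
        a = rng.random((1, 5, 5))
        np.testing.assert_array_equal(combine_heads(a), a[0])

    def test_max_dominates_each_head(self, rng):
        a = rng.random((3, 6, 6))
        out = combine_heads(a)
        for h in range(3):
            assert np.all(out >= a[h])

    def test_complementary_heads(self, rng):
        a0 = rng.random((4, 4))
        out = combine_heads(np.stack([a0, 1 - a0]))
        assert np.all(out >= 0.5)


class TestSelectCandidates:
    def test_constant_matrix_empty(self):
        assert select_candidates(np.full((5, 5), 0.2)) == []

    def test_borderline_two_by_two(self):
        # mean is 0.5; best off-diagonal value is exactly 0.5, not above it
        m = np.array([[0.9, 0.1], [0.5, 0.5]])
        assert select_candidates(m) == []

    def test_single_spike(self):
        m = np.zeros((10, 10))
        m[2, 7] = 0.9
        assert select_candidates(m) == [(2, 7, 0.9)]

    def test_direction_symmetrization(self):
        m = np.zeros((4, 4))
        m[3, 1] = 0.8  # only the lower triangle is populated
        out = select_candidates(m)
        assert out == [(1, 3, 0.8)]

    def test_non_finite_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = np.inf
        with pytest.raises(ValueError):
            select_candidates(m)


class TestPositionsToFilters:
    def test_one_active_filter_each_end(self):
        act = np.zeros((4, 10))
        act[1, 2] = 1.0
        act[3, 7] = 1.0
        fmax = np.ones(4)
        pairs = positions_to_filters([(2, 7, 0.5)], act, fmax)
        assert pairs == {(1, 3): 0.5}

    def test_cross_product_count(self):
        act = np.zeros((6, 10))
        act[[0, 1], 2] = 1.0
        act[[2, 3, 4], 7] = 1.0
        pairs = positions_to_filters([(2, 7, 0.4)], act, np.ones(6))
        assert len(pairs) == 6

    def test_self_pair_dropped(self):
        act = np.zeros((3, 10))
        act[1, 2] = 1.0
        act[1, 7] = 1.0
        assert positions_to_filters([(2, 7, 0.4)], act, np.ones(3)) == {}

    def test_activation_threshold(self):
        act = np.zeros((2, 10))
        act[0, 2] = 0.64  # below 0.65 of max 1.0
        act[1, 7] = 0.70
        assert positions_to_filters([(2, 7, 0.9)], act, np.ones(2)) == {}


class _StubModel:
    """Quadratic read-out of the attention matrix: F = sum(A^2)."""

    def __init__(self, attention):
        self.attention = np.asarray(attention)

        class _Spec:
            n_outputs = 1
        self.spec = _Spec()

    def set_training(self, flag):
        pass

    def forward(self, x):
        class _Out:
            pass
        out = _Out()
        out.attention = self.attention
        out.predictions = np.ones((self.attention.shape[0], 1))
        return out

    def forward_graph(self, x, attn_override=None):
        a = attn_override
        logits = (a * a).sum(axis=(1, 2, 3)).reshape(-1, 1)
        return logits, a, None


class _LinearStub(_StubModel):
    """F = sum(C ⊙ A) with a fixed coefficient matrix C."""

    def __init__(self, attention, coeff):
        super().__init__(attention)
        self.coeff = np.asarray(coeff)

    def forward_graph(self, x, attn_override=None):
        a = attn_override
        logits = (a * Tensor(self.coeff)).sum(axis=(1, 2, 3)).reshape(-1, 1)
        return logits, a, None


class TestAttribution:
    def test_quadratic_closed_form(self, rng):
        # F(A) = sum A^2: sum_{t=1..m} 2 t/m = m+1, so Attr = A^2 (m+1)/m
        a = rng.random((2, 2, 4, 4))
        model = _StubModel(a)
        attr = attention_attribution(model, np.zeros((2, 4, 4)), m=20)
        np.testing.assert_allclose(attr, 1.05 * a * a, atol=1e-10)

    def test_linear_model_exact_any_m(self, rng):
        a = rng.random((1, 1, 5, 5))
        c = rng.normal(size=(1, 1, 5, 5))
        model = _LinearStub(a, c)
        for m in (1, 3, 20):
            attr = attention_attribution(model, np.zeros((1, 5, 5)), m=m)
            np.testing.assert_allclose(attr, a * c, atol=1e-12)

    def test_zero_attention_zero_attribution(self):
        model = _StubModel(np.zeros((1, 1, 3, 3)))
        attr = attention_attribution(model, np.zeros((1, 3, 3)), m=5)
        np.testing.assert_array_equal(attr, 0)

    def test_real_model_shapes_not_row_stochastic(self, tiny_trained):
        result, splits, truth, lib = tiny_trained
        seqs = splits[2].sequences[:4]
        attr = attention_attribution(result.model, seqs, m=4)
        out = result.model.forward(seqs)
        assert attr.shape == out.attention.shape
        assert np.all(np.isfinite(attr))


class TestDinucShuffle:
    def test_homopolymer_fixed_point(self, rng):
        assert dinuc_shuffle("AAAA", rng) == "AAAA"

    @pytest.mark.parametrize("seed", range(5))
    def test_dinucleotide_counts_preserved(self, seed):
        rng = np.random.default_rng(seed)
        seq = ma.generate_background(200, (0.3, 0.2, 0.2, 0.3), rng)
        shuf = dinuc_shuffle(seq, rng)
        assert len(shuf) == len(seq)

        def counts(s):
            c = {}
            for d in zip(s, s[1:]):
                c[d] = c.get(d, 0) + 1
            return c

        assert counts(seq) == counts(shuf)

    def test_deterministic(self):
        seq = "ACGTACGTTGCAACGT"
        a = dinuc_shuffle(seq, np.random.default_rng(3))
        b = dinuc_shuffle(seq, np.random.default_rng(3))
        assert a == b

    def test_actually_shuffles(self):
        seq = ma.generate_background(300, (0.25,) * 4,
                                     np.random.default_rng(0))
        shuffled = {dinuc_shuffle(seq, np.random.default_rng(s))
                    for s in range(5)}
        assert len(shuffled) > 1


def brute_force_mw_p(fg, bg):
    """Exact permutation tail probability for U(fg, bg) >= observed."""
    pooled = np.concatenate([fg, bg])
    n, k = len(pooled), len(fg)

    def u(a, b):
        d = np.subtract.outer(a, b)
        return (d > 0).sum() + 0.5 * (d == 0).sum()

    obs = u(np.asarray(fg), np.asarray(bg))
    hits = 0
    for idx in itertools.combinations(range(n), k):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        hits += u(pooled[mask], pooled[~mask]) >= obs - 1e-12
    return hits / comb(n, k)


class TestMannWhitney:
    def test_textbook_separated_samples(self):
        assert mann_whitney_p([5, 6, 7], [1, 2, 3]) == pytest.approx(1 / 20)

    def test_single_observation(self):
        assert mann_whitney_p([3], [1, 2]) == pytest.approx(1 / 3)

    def test_identical_samples_not_significant(self):
        assert mann_whitney_p([2, 2, 2], [2, 2, 2]) == 1.0
        assert mann_whitney_p([1, 2, 3], [1, 2, 3]) >= 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        k = int(rng.integers(1, n))
        vals = rng.integers(0, 4, size=n).astype(float)  # heavy ties
        fg, bg = vals[:k], vals[k:]
        assert mann_whitney_p(fg, bg) == pytest.approx(
            brute_force_mw_p(fg, bg))

    def test_large_sample_agrees_with_scipy(self, rng):
        from scipy.stats import mannwhitneyu
        fg = rng.normal(0.3, 1, 60)
        bg = rng.normal(0, 1, 80)
        ours = mann_whitney_p(fg, bg)
        ref = mannwhitneyu(fg, bg, alternative="greater",
                           method="asymptotic").pvalue
        assert ours == pytest.approx(ref)


class TestTestInteractions:
    def test_min_support_filters(self):
        fg = {(0, 1): [1.0] * 3, (0, 2): [1.0] * 6}
        bg = {(0, 1): [0.1] * 6, (0, 2): [0.1] * 6}
        tab = run_interaction_tests(fg, bg, min_support=5, keep_all=True)
        assert list(zip(tab.filter_a, tab.filter_b)) == [(0, 2)]

    def test_missing_background_uses_pooled_fallback(self):
        fg = {(0, 1): [0.9] * 8}
        bg = {(2, 3): [0.1] * 10}
        tab = run_interaction_tests(fg, bg, keep_all=True)
        assert len(tab) == 1
        assert tab.p_value.iloc[0] < 0.01

    def test_alpha_zero_empty(self):
        fg = {(0, 1): [0.9] * 8}
        bg = {(0, 1): [0.1] * 8}
        assert len(run_interaction_tests(fg, bg, alpha=0.0)) == 0

    def test_q_values_in_unit_interval(self, rng):
        fg = {(i, i + 1): list(rng.random(8)) for i in range(6)}
        bg = {(i, i + 1): list(rng.random(8)) for i in range(6)}
        tab = run_interaction_tests(fg, bg, keep_all=True)
        assert ((tab.q_value >= 0) & (tab.q_value <= 1)).all()

    def test_permutation_equivariance(self, rng):
        pairs = [(0, 1), (1, 2), (0, 3)]
        fg = {p: list(rng.random(8) + 0.3) for p in pairs}
        bg = {p: list(rng.random(8)) for p in pairs}
        tab = run_interaction_tests(fg, bg, keep_all=True)
        relabel = {0: 7, 1: 5, 2: 6, 3: 4}
        fg2 = {tuple(sorted((relabel[a], relabel[b]))): v
               for (a, b), v in fg.items()}
        bg2 = {tuple(sorted((relabel[a], relabel[b]))): v
               for (a, b), v in bg.items()}
        tab2 = run_interaction_tests(fg2, bg2, keep_all=True)
        key = lambda t: sorted(map(tuple, t[["n_support", "p_value",
                                             "q_value"]].values.tolist()))
        assert key(tab) == key(tab2)


class TestEndToEnd:
    def test_implanted_pairs_recovered(self, tiny_trained):
        """A model trained on a small pair dataset reports the implanted
        pairs among its significant interactions."""
        result, splits, truth, lib = tiny_trained
        inter = ma.infer_interactions(result.model, splits[2], library=lib,
                                      rng=0)
        assert truth.pairs & inter.predicted_pairs

    def test_reported_pairs_within_pool(self, tiny_trained):
        result, splits, truth, lib = tiny_trained
        inter = ma.infer_interactions(result.model, splits[2], library=lib,
                                      rng=0)
        pool = set(lib.names)
        for a, b in inter.predicted_pairs:
            assert a in pool and b in pool

    def test_raw_and_attribution_share_structure(self, tiny_trained):
        result, splits, truth, lib = tiny_trained
        raw = ma.infer_interactions(result.model, splits[2], library=lib,
                                    rng=0)
        attr = ma.infer_interactions(result.model, splits[2], library=lib,
                                     mode="attribution", attribution_steps=5,
                                     rng=0)
        assert list(raw.motif_table.columns) == list(attr.motif_table.columns)
        assert raw.n_foreground == attr.n_foreground
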