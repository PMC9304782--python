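"""Skip-gram tuple generation (subsampling, windows, negatives) and the
shared-matrix embedding trainer (gradients, descent, determinism)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crcs.embedding import (
    EmbeddingConfig,
    SkipGramTuple,
    SubsamplingParams,
    TupleGenConfig,
    bce_loss_and_grads,
    keep_probability,
    make_tuples,
    n_trainable_parameters,
    select_centers,
    switch_frequencies,
    train_embeddings,
)
from crcs.models import CodonSwitchSequence


def seq_of(indices):
    return CodonSwitchSequence("t", list(indices))


class TestFrequencies:
    def test_counting(self):
        f = switch_frequencies([seq_of([5, 5, 7])])
        assert f[5] == pytest.approx(2 / 3)
        assert f[7] == pytest.approx(1 / 3)
        assert f[0] == 0.0

    def test_normalization(self):
        rng = np.random.default_rng(0)
        corpus = [seq_of(rng.integers(0, 640, size=20)) for _ in range(5)]
        assert switch_frequencies(corpus).sum() == pytest.approx(1.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            switch_frequencies([])


class TestKeepProbability:
    def test_at_epsilon_is_one(self):
        assert keep_probability(0.001) == 1.0

    def test_printed_example_value(self):
        # sqrt(1 + 0.1/0.001) * 0.001/0.1 = sqrt(101) * 0.01
        assert keep_probability(0.1) == pytest.approx(0.100499, abs=1e-6)

    def test_zero_frequency_limit(self):
        assert keep_probability(0.0) == 1.0

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            keep_probability(-0.1)

    @given(
        st.floats(min_value=0.0011, max_value=0.99),
        st.floats(min_value=0.0011, max_value=0.99),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_decreasing_above_epsilon(self, f1, f2):
        lo, hi = sorted((f1, f2))
        assert keep_probability(lo) >= keep_probability(hi)


class TestSelectCenters:
    def test_rare_switches_always_selected(self):
        freqs = np.full(640, 1e-4)
        s = seq_of([1, 2, 3, 4])
        rng = np.random.default_rng(0)
        assert select_centers(s, freqs, SubsamplingParams(), rng) == [0, 1, 2, 3]

    def test_seeded_determinism(self):
        freqs = np.zeros(640)
        freqs[9] = 0.9
        s = seq_of([9] * 50)
        a = select_centers(s, freqs, SubsamplingParams(), np.random.default_rng(4))
        b = select_centers(s, freqs, SubsamplingParams(), np.random.default_rng(4))
        assert a == b

    def test_selection_rate_matches_binomial_oracle(self):
        f = 1.0
        p = keep_probability(f)  # ~= 0.0316
        freqs = np.zeros(640)
        freqs[3] = f
        n = 20000
        s = seq_of([3] * n)
        rng = np.random.default_rng(8)
        k = len(select_centers(s, freqs, SubsamplingParams(), rng))
        se = math.sqrt(n * p * (1 - p))
        assert abs(k - n * p) < 3 * se


class TestMakeTuples:
    CFG = TupleGenConfig(ws=3, nsr=0.2, seed=0)

    def test_interior_center_counts(self):
        s = seq_of(range(10))
        t = make_tuples(s, [5], self.CFG, np.random.default_rng(0))
        pos = [x for x in t if x.label == 1]
        neg = [x for x in t if x.label == 0]
        assert len(pos) == 6  # 2 * ws
        assert len(neg) == 2  # ceil(7 * 0.2)

    def test_corner_center_truncated_window(self):
        s = seq_of(range(10))
        t = make_tuples(s, [0], self.CFG, np.random.default_rng(0))
        assert sum(x.label for x in t) == 3

    def test_brute_force_window_oracle(self):
        """Positive tuples agree with naive window enumeration on random
        sequences of random lengths."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            idx = list(rng.integers(0, 640, size=n))
            s = seq_of(idx)
            centers = list(rng.choice(n, size=min(n, 4), replace=False))
            got = make_tuples(s, centers, self.CFG, np.random.default_rng(1))
            expected_pos = []
            for c in centers:
                for j in range(max(0, c - 3), min(n, c + 4)):
                    if j != c:
                        expected_pos.append((idx[c], idx[j]))
            assert [(t.center, t.partner) for t in got if t.label == 1] == expected_pos
            assert sum(1 for t in got if t.label == 0) == 2 * len(centers)

    def test_all_positive_partners_within_window(self):
        rng = np.random.default_rng(3)
        idx = list(rng.integers(0, 640, size=40))
        s = seq_of(idx)
        tuples = make_tuples(s, range(40), self.CFG, rng)
        # reconstruct: every label-1 pair must occur as (idx[c], idx[j]) with
        # |c - j| <= ws for some c, j
        pairs = {(idx[c], idx[j]) for c in range(40)
                 for j in range(max(0, c - 3), min(40, c + 4)) if j != c}
        assert all((t.center, t.partner) in pairs for t in tuples if t.label == 1)


class TestTrainer:
    def test_parameter_count_at_default_length(self):
        assert n_trainable_parameters(300) == 192_002
        assert n_trainable_parameters(24) == 640 * 24 + 2

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(640, 4))
        w, b = 0.7, -0.1
        centers, partners, labels = [1, 2, 3], [4, 1, 600], [1, 0, 1]
        loss, dE, dw, db = bce_loss_and_grads(E, w, b, centers, partners, labels)
        eps = 1e-6

        def f(E_, w_, b_):
            l, *_ = bce_loss_and_grads(E_, w_, b_, centers, partners, labels)
            return l

        for (i, j) in [(1, 0), (4, 3), (600, 2), (2, 1)]:
            Ep = E.copy(); Ep[i, j] += eps
            Em = E.copy(); Em[i, j] -= eps
            fd = (f(Ep, w, b) - f(Em, w, b)) / (2 * eps)
            assert dE[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-9)
        assert dw == pytest.approx((f(E, w + eps, b) - f(E, w - eps, b)) / (2 * eps), rel=1e-5)
        assert db == pytest.approx((f(E, w, b + eps) - f(E, w, b - eps)) / (2 * eps), rel=1e-5)

    def _toy_tuples(self):
        # separable: (1,2) and (3,4) in-window, everything else negative
        out = []
        for _ in range(30):
            out += [SkipGramTuple(1, 2, 1), SkipGramTuple(2, 1, 1),
                    SkipGramTuple(3, 4, 1), SkipGramTuple(1, 5, 0),
                    SkipGramTuple(2, 6, 0), SkipGramTuple(3, 7, 0)]
        return out

    def test_loss_decreases_on_separable_tuples(self):
        history = []
        train_embeddings(
            self._toy_tuples(),
            EmbeddingConfig(embedding_length=8, epochs=5, seed=0),
            loss_history=history,
        )
        assert history[4] < history[0]

    def test_seeded_training_is_deterministic(self):
        cfg = EmbeddingConfig(embedding_length=8, epochs=3, seed=5)
        a = train_embeddings(self._toy_tuples(), cfg)
        b = train_embeddings(self._toy_tuples(), cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_tuples_rejected(self):
        with pytest.raises(ValueError):
            train_embeddings([], EmbeddingConfig(embedding_length=4))

    def test_cooccurrence_geometry(self):
        """Switches that always co-occur end up closer (cosine) than
        switches that never do."""
        rng = np.random.default_rng(2)
        tuples = []
        for _ in range(200):
            tuples += [SkipGramTuple(10, 11, 1), SkipGramTuple(11, 10, 1)]
            tuples += [SkipGramTuple(10, int(rng.integers(100, 640)), 0)]
            tuples += [SkipGramTuple(12, int(rng.integers(100, 640)), 0)]
            tuples += [SkipGramTuple(12, 13, 1)]
        emb = train_embeddings(
            tuples, EmbeddingConfig(embedding_length=8, epochs=30, seed=0)
        )
        e = emb.values

        def cos(i, j):
            return e[i] @ e[j] / (np.linalg.norm(e[i]) * np.linalg.norm(e[j]))

        assert cos(10, 11) > cos(10, 12)
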