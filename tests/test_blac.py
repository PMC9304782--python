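"""Classifier workflow: training-set filters, gene-disjoint folds, the
average-precision metric against an exhaustive oracle, threshold metrics,
score-distribution comparison, and cross-validated signal recovery."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import average_precision_score

from crcs.blac import (
    BLACArchSpec,
    FingerprintMismatchError,
    ScoredVariant,
    TrainConfig,
    assign_gene_folds,
    average_precision,
    build_blac,
    compare_distributions,
    filter_training_set,
    threshold_metrics,
    train_blac,
)
from crcs.embedding import EmbeddingMatrix
from crcs.models import CodonSwitchSequence


def seq(n, gene="G"):
    return CodonSwitchSequence("t", [0] * n, gene_symbol=gene)


class TestFilterTrainingSet:
    def test_length_cut_is_strict(self):
        cfg = TrainConfig(max_len=1500, min_gene_variants=1)
        kept = filter_training_set([seq(1500), seq(1499)], cfg)
        assert [len(s) for s in kept] == [1499]

    def test_min_gene_variant_count(self):
        cfg = TrainConfig(max_len=1500, min_gene_variants=200)
        seqs = [seq(10, "A") for _ in range(199)] + [seq(10, "B") for _ in range(200)]
        kept = filter_training_set(seqs, cfg)
        assert {s.gene_symbol for s in kept} == {"B"}

    def test_empty_input(self):
        assert filter_training_set([], TrainConfig()) == []


class TestGeneFolds:
    def test_partition_into_near_equal_folds(self):
        fa = assign_gene_folds([f"g{i}" for i in range(8)], 4, seed=0)
        sizes = [len(fa.genes_in_fold(k)) for k in range(4)]
        assert sizes == [2, 2, 2, 2]

    def test_folds_are_disjoint_and_cover(self):
        genes = [f"g{i}" for i in range(11)]
        fa = assign_gene_folds(genes, 4, seed=1)
        all_assigned = [g for k in range(4) for g in fa.genes_in_fold(k)]
        assert sorted(all_assigned) == sorted(genes)
        assert max(len(fa.genes_in_fold(k)) for k in range(4)) - min(
            len(fa.genes_in_fold(k)) for k in range(4)
        ) <= 1

    def test_seed_determinism_and_too_few_genes(self):
        genes = ["a", "b", "c", "d", "e"]
        assert assign_gene_folds(genes, 2, 9).gene_to_fold == assign_gene_folds(genes, 2, 9).gene_to_fold
        with pytest.raises(ValueError):
            assign_gene_folds(["a"], 2)


class TestAveragePrecision:
    def test_hand_example(self):
        assert average_precision([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(
            (1 + 2 / 3) / 2
        )

    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_prevalence(self):
        assert average_precision([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.1, 0.2], [0, 0])

    def test_exhaustive_oracle_small_inputs(self):
        """Agrees with a rank-by-rank oracle (and sklearn) on every label
        pattern over distinct scores of length <= 8."""
        for n in (2, 4, 6, 8):
            scores = np.linspace(1.0, 0.1, n)
            for labels in itertools.product([0, 1], repeat=n):
                if sum(labels) == 0:
                    continue
                # oracle: mean of precision at each positive in rank order
                tp = 0
                precisions = []
                for rank, y in enumerate(labels, start=1):
                    if y:
                        tp += 1
                        precisions.append(tp / rank)
                oracle = sum(precisions) / sum(labels)
                got = average_precision(scores, list(labels))
                assert got == pytest.approx(oracle)
                assert got == pytest.approx(
                    average_precision_score(list(labels), scores)
                )

    def test_label_permutation_null_centers_on_prevalence(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        labels = np.array([1] * 60 + [0] * 140)
        aps = []
        for _ in range(50):
            rng.shuffle(labels)
            aps.append(average_precision(scores, labels))
        assert np.mean(aps) == pytest.approx(0.3, abs=0.03)


class TestThresholdMetrics:
    def _scored(self, scores, labels):
        return [
            ScoredVariant(("c", i, "A", "G"), "t", s, l, 0)
            for i, (s, l) in enumerate(zip(scores, labels))
        ]

    def test_perfect_separation(self):
        sv = self._scored([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert threshold_metrics(sv, 0.9) == (1.0, 1.0, 1.0)

    def test_zero_threshold_has_full_sensitivity(self):
        sv = self._scored([0.2, 0.8, 0.5], [1, 0, 1])
        sens, _, _ = threshold_metrics(sv, 0.0)
        assert sens == 1.0

    def test_confusion_arithmetic(self):
        # 2 TP, 1 FN, 1 FP -> F1 = 4/6
        sv = self._scored([0.95, 0.92, 0.3, 0.91], [1, 1, 1, 0])
        sens, spec, f1 = threshold_metrics(sv, 0.9)
        assert sens == pytest.approx(2 / 3)
        assert spec == 0.0
        assert f1 == pytest.approx(2 / 3)


class TestCompareDistributions:
    def test_exact_enumeration_example(self):
        assert compare_distributions([3, 4], [1, 2]) == pytest.approx(1 / 6)

    def test_identical_multisets_symmetric(self):
        p = compare_distributions([1, 2, 3], [1, 2, 3])
        assert 0.4 <= p <= 0.75

    def test_exact_and_asymptotic_branches_agree(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(size=6)
        exact = compare_distributions(a, b)
        approx = float(
            sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue
        )
        assert exact == pytest.approx(approx, abs=0.02)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=5), rng.normal(size=6)
        ours = compare_distributions(a, b)
        scipy_p = float(
            sps.mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
        )
        assert ours == pytest.approx(scipy_p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestTraining:
    ARCH = BLACArchSpec(16, 16, 8, 8)

    def test_fingerprint_mismatch_rejected(self):
        emb = EmbeddingMatrix(np.zeros((640, 4)), dict_fingerprint="aaa")
        with pytest.raises(FingerprintMismatchError):
            build_blac(emb, self.ARCH, expected_fingerprint="bbb")

    def test_single_class_fold_rejected(self):
        emb = EmbeddingMatrix(np.random.default_rng(0).normal(size=(640, 4)))
        model = build_blac(emb, self.ARCH)
        seqs = [seq(5, "A"), seq(6, "B")]
        with pytest.raises(ValueError):
            model.fit(seqs, [1, 1], TrainConfig(epochs=1, min_gene_variants=1))

    def test_gene_fold_hygiene_and_signal_recovery(self, signal_study):
        """Out-of-fold AP on strongly planted data is high, every sequence
        is scored exactly once, and no scoring model saw its gene."""
        seqs, labels, emb = signal_study.seqs, signal_study.labels, signal_study.emb
        cfg = TrainConfig(folds=4, epochs=8, min_gene_variants=1, seed=2)
        folds = assign_gene_folds([s.gene_symbol for s in seqs], 4, seed=2)
        _, scored = train_blac(seqs, labels, folds, emb, self.ARCH, cfg)
        assert len(scored) == len(seqs)
        for sv in scored:
            assert folds.fold_of(sv.gene_symbol) == sv.fold
        ap = average_precision([s.score for s in scored], [s.label for s in scored])
        assert ap > 0.8

    def test_seeded_rerun_reproduces_scores(self, signal_study):
        seqs, labels, emb = signal_study.seqs[:80], signal_study.labels[:80], signal_study.emb
        cfg = TrainConfig(folds=2, epochs=2, min_gene_variants=1, seed=3)
        folds = assign_gene_folds([s.gene_symbol for s in seqs], 2, seed=3)
        _, a = train_blac(seqs, labels, folds, emb, self.ARCH, cfg)
        _, b = train_blac(seqs, labels, folds, emb, self.ARCH, cfg)
        assert [s.score for s in a] == [s.score for s in b]
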