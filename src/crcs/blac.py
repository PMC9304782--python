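"""BLAC: bi-LSTM attention classifier over frozen codon-switch embeddings.

The network stack is: frozen embedding lookup -> bi-LSTM -> batch norm ->
bi-LSTM -> batch norm -> time-distributed dense -> batch norm -> additive
attention -> dense sigmoid scalar.  The embedding rows are never updated.
Sequences are variable-length; batches bucket by length and pad, with all
padded steps masked out of normalization statistics, attention and the loss.

Evaluation follows gene-disjoint cross-validation: genes are partitioned
into folds and every sequence is scored exactly once, by the model whose
training fold excluded its gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _nn
from .embedding import EmbeddingMatrix
from .models import CodonSwitchSequence
from .stats import mannwhitney_greater

logger = logging.getLogger("crcs")

__all__ = [
    "BLACArchSpec",
    "TrainConfig",
    "FoldAssignment",
    "ScoredVariant",
    "BLACModel",
    "build_blac",
    "filter_training_set",
    "assign_gene_folds",
    "train_blac",
    "average_precision",
    "fake_split_control",
    "threshold_metrics",
    "compare_distributions",
]


@dataclass(frozen=True)
class BLACArchSpec:
    lstm1_units: int = 64
    lstm2_units: int = 64
    td_dense_units: int = 32
    attention_dim: int = 32

    def __post_init__(self) -> None:
        if min(self.lstm1_units, self.lstm2_units, self.td_dense_units, self.attention_dim) < 1:
            raise ValueError("all layer widths must be positive")


@dataclass
class TrainConfig:
    folds: int = 4
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    max_len: int = 1500
    min_gene_variants: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")


@dataclass
class FoldAssignment:
    """Mapping gene symbol -> fold id; a partition into near-equal folds."""

    gene_to_fold: dict[str, int]
    k: int

    def genes_in_fold(self, fold: int) -> set[str]:
        return {g for g, f in self.gene_to_fold.items() if f == fold}

    def fold_of(self, gene: str) -> int:
        return self.gene_to_fold[gene]


@dataclass(frozen=True)
class ScoredVariant:
    variant_key: tuple
    transcript_id: str
    score: float
    label: int
    fold: int = -1
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


class FingerprintMismatchError(ValueError):
    """Embedding matrix was trained against a different dictionary ordering."""


class BLACModel:
    """The assembled classifier network with its (frozen) embedding."""

    def __init__(self, emb: EmbeddingMatrix, arch: BLACArchSpec, seed: int = 0):
        self.emb = emb
        self.arch = arch
        rng = np.random.default_rng(seed)
        L = emb.L
        self.lstm1 = _nn.BiLSTM(L, arch.lstm1_units, rng)
        self.bn1 = _nn.MaskedBatchNorm(2 * arch.lstm1_units)
        self.lstm2 = _nn.BiLSTM(2 * arch.lstm1_units, arch.lstm2_units, rng)
        self.bn2 = _nn.MaskedBatchNorm(2 * arch.lstm2_units)
        self.td = _nn.TimeDistributedDense(2 * arch.lstm2_units, arch.td_dense_units, rng)
        self.bn3 = _nn.MaskedBatchNorm(arch.td_dense_units)
        self.attention = _nn.AdditiveAttention(arch.td_dense_units, arch.attention_dim, rng)
        self.head = _nn.SigmoidHead(arch.td_dense_units, rng)
        self._layers = [
            self.lstm1, self.bn1, self.lstm2, self.bn2, self.td, self.bn3,
            self.attention, self.head,
        ]

    # -- plumbing -----------------------------------------------------------

    def params(self) -> list[_nn.Param]:
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def n_trainable_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _pad(self, seqs: Sequence[Sequence[int]], pad_to: Optional[int] = None):
        lengths = [len(s) for s in seqs]
        T = max(max(lengths), pad_to or 0)
        B = len(seqs)
        idx = np.zeros((B, T), dtype=int)
        mask = np.zeros((B, T), dtype=bool)
        for i, s in enumerate(seqs):
            idx[i, : len(s)] = s
            mask[i, : len(s)] = True
        return idx, mask

    def forward_logits(
        self,
        seqs: Sequence[Sequence[int]],
        train: bool,
        pad_to: Optional[int] = None,
    ) -> np.ndarray:
        idx, mask = self._pad(seqs, pad_to)
        X = self.emb.values[idx]  # frozen lookup; no gradient flows back
        h = self.lstm1.forward(X, mask)
        h = self.bn1.forward(h, mask, train)
        h = self.lstm2.forward(h, mask)
        h = self.bn2.forward(h, mask, train)
        h = self.td.forward(h)
        h = self.bn3.forward(h, mask, train)
        ctx = self.attention.forward(h, mask)
        return self.head.forward(ctx)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.attention.backward(d)
        d = self.bn3.backward(d)
        d = self.td.backward(d)
        d = self.bn2.backward(d)
        d = self.lstm2.backward(d)
        d = self.bn1.backward(d)
        self.lstm1.backward(d)

    # -- training and scoring ----------------------------------------------

    def fit(
        self,
        seqs: Sequence[CodonSwitchSequence],
        labels: Sequence[int],
        cfg: TrainConfig,
        rng: Optional[np.random.Generator] = None,
    ) -> list[float]:
        labels = np.asarray(labels, dtype=float)
        if len(set(labels.tolist())) < 2:
            raise ValueError("training fold contains a single class")
        rng = rng or np.random.default_rng(cfg.seed)
        order = np.argsort([len(s) for s in seqs], kind="stable")
        batches = [
            order[i : i + cfg.batch_size] for i in range(0, len(order), cfg.batch_size)
        ]
        opt = _nn.Adam(self.params(), lr=cfg.learning_rate)
        history = []
        indices = [s.switch_indices for s in seqs]
        for _ in range(cfg.epochs):
            rng.shuffle(batches)
            total = 0.0
            for batch in batches:
                opt.zero_grad()
                logits = self.forward_logits([indices[i] for i in batch], train=True)
                loss, dz = _nn.bce_with_logits(logits, labels[batch])
                self.backward(dz)
                opt.step()
                total += loss * len(batch)
            history.append(total / len(seqs))
        return history

    def predict(
        self, seqs: Sequence[CodonSwitchSequence], batch_size: int = 64
    ) -> np.ndarray:
        indices = [s.switch_indices for s in seqs]
        order = np.argsort([len(s) for s in indices], kind="stable")
        scores = np.zeros(len(indices))
        for i in range(0, len(order), batch_size):
            batch = order[i : i + batch_size]
            logits = self.forward_logits([indices[j] for j in batch], train=False)
            scores[batch] = _nn.sigmoid(logits)
        return scores


def build_blac(
    emb: EmbeddingMatrix,
    arch: BLACArchSpec = BLACArchSpec(),
    seed: int = 0,
    expected_fingerprint: Optional[str] = None,
) -> BLACModel:
    """Assemble a classifier on a frozen embedding matrix.

    If *expected_fingerprint* is given (the encoder dictionary's ordering
    fingerprint), a mismatch with the matrix's own tag is an error.
    """
    if (
        expected_fingerprint
        and emb.dict_fingerprint
        and emb.dict_fingerprint != expected_fingerprint
    ):
        raise FingerprintMismatchError(
            "embedding matrix fingerprint does not match the encoder dictionary"
        )
    return BLACModel(emb, arch, seed=seed)


def filter_training_set(
    seqs: Sequence[CodonSwitchSequence], cfg: TrainConfig
) -> list[CodonSwitchSequence]:
    """Keep sequences shorter than max_len from genes with enough variants.

    Length is strict (< max_len); the per-gene count (splice variants
    included) must reach min_gene_variants after the length cut.
    """
    short = [s for s in seqs if len(s) < cfg.max_len]
    counts: dict[str, int] = {}
    for s in short:
        counts[s.gene_symbol] = counts.get(s.gene_symbol, 0) + 1
    kept = [s for s in short if counts[s.gene_symbol] >= cfg.min_gene_variants]
    logger.info(
        "filter_training_set: %d -> %d sequences (%d genes retained)",
        len(seqs), len(kept), len({s.gene_symbol for s in kept}),
    )
    return kept


def assign_gene_folds(genes: Sequence[str], k: int, seed: int = 0) -> FoldAssignment:
    """Randomly partition genes into k near-equal folds (deterministic)."""
    genes = sorted(set(genes))
    if len(genes) < k:
        raise ValueError(f"cannot make {k} folds from {len(genes)} genes")
    rng = np.random.default_rng(seed)
    order = list(genes)
    rng.shuffle(order)
    return FoldAssignment({g: i % k for i, g in enumerate(order)}, k)


def train_blac(
    seqs: Sequence[CodonSwitchSequence],
    labels: Sequence[int],
    folds: FoldAssignment,
    emb: EmbeddingMatrix,
    arch: BLACArchSpec = BLACArchSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[list[BLACModel], list[ScoredVariant]]:
    """Gene-disjoint cross-validated training.

    Returns one trained model per fold plus out-of-fold scored variants:
    every sequence is scored exactly once, by the model whose training set
    excluded its gene.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(seqs):
        raise ValueError("labels and sequences differ in length")
    models = []
    scored: list[ScoredVariant] = []
    for fold in range(folds.k):
        val_genes = folds.genes_in_fold(fold)
        train_idx = [i for i, s in enumerate(seqs) if s.gene_symbol not in val_genes]
        val_idx = [i for i, s in enumerate(seqs) if s.gene_symbol in val_genes]
        model = build_blac(emb, arch, seed=cfg.seed + fold)
        model.fit(
            [seqs[i] for i in train_idx],
            labels[train_idx],
            cfg,
            rng=np.random.default_rng(cfg.seed + fold),
        )
        models.append(model)
        if not val_idx:
            continue
        val_scores = model.predict([seqs[i] for i in val_idx])
        for i, sc in zip(val_idx, val_scores):
            s = seqs[i]
            scored.append(
                ScoredVariant(
                    variant_key=s.variant_key or ("", -1, "", ""),
                    transcript_id=s.transcript_id,
                    score=float(np.clip(sc, 0.0, 1.0)),
                    label=int(labels[i]),
                    fold=fold,
                    gene_symbol=s.gene_symbol,
                )
            )
    return models, scored


def average_precision(scores, labels) -> float:
    """Area under the precision-recall curve.

    Computed as the mean, over positives in descending score order, of the
    precision at each positive; tied scores are treated as one threshold
    group, so a constant scorer earns the positive prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        d_tp = int(y[i:j].sum())
        d_fp = (j - i) - d_tp
        tp += d_tp
        fp += d_fp
        if d_tp:
            ap += d_tp * tp / (tp + fp)
        i = j
    return ap / n_pos


def fake_split_control(
    pool: Sequence[CodonSwitchSequence],
    emb: EmbeddingMatrix,
    arch: BLACArchSpec = BLACArchSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> float:
    """No-signal control: random pseudo-classes from a homogeneous pool.

    The pool is randomly halved into balanced pseudo-classes, the full
    gene-disjoint cross-validation cycle is run, and the out-of-fold average
    precision is returned; with no real signal it concentrates near 0.5.
    """
    n = len(pool)
    if n < 4 * cfg.folds:
        raise ValueError(f"pool of {n} sequences is too small for {cfg.folds} folds")
    rng = np.random.default_rng(cfg.seed)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[: n // 2]] = 1
    pool = [s.with_label(int(l)) for s, l in zip(pool, labels)]
    folds = assign_gene_folds([s.gene_symbol for s in pool], cfg.folds, seed=cfg.seed)
    _, scored = train_blac(pool, labels, folds, emb, arch, cfg)
    return average_precision([s.score for s in scored], [s.label for s in scored])


def threshold_metrics(scored: Sequence[ScoredVariant], threshold: float):
    """(sensitivity, specificity, F1) with score >= threshold called positive."""
    scores = np.array([s.score for s in scored])
    labels = np.array([s.label for s in scored])
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return sens, spec, f1


def compare_distributions(scores_a, scores_b) -> float:
    """One-sided Mann-Whitney U p-value for 'a stochastically greater than b'."""
    return mannwhitney_greater(scores_a, scores_b)
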