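"""Skip-gram-as-classification embedding of codon switches.

Training pairs (center, partner) are built from codon switch sequences:
partners inside a +-ws window around a subsampled center are positives
(label 1); for every center, ceil((2*ws+1)*nsr) partners drawn uniformly
from the 640-entry dictionary are negatives (label 0).  A single shared
640 x L embedding matrix is trained by logistic regression on the pair dot
product: p = sigmoid(w * <e_center, e_partner> + b), minimising binary
cross-entropy with ADAM.  The trainable parameters are the matrix plus the
two scalars w and b — 640*L + 2 in total (192,002 at L = 300).

Centers are subsampled to tame the heavy skew towards identity switches:
a switch with relative corpus frequency f is kept with probability
min(1, sqrt(1 + f/eps) * eps / f), eps = 0.001 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .dictionary import DICTIONARY_SIZE
from .models import CodonSwitchSequence

__all__ = [
    "SubsamplingParams",
    "TupleGenConfig",
    "EmbeddingConfig",
    "EmbeddingMatrix",
    "SkipGramTuple",
    "switch_frequencies",
    "keep_probability",
    "select_centers",
    "make_tuples",
    "corpus_tuples",
    "train_embeddings",
    "n_trainable_parameters",
]


@dataclass(frozen=True)
class SubsamplingParams:
    epsilon: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")


@dataclass(frozen=True)
class TupleGenConfig:
    ws: int = 3
    nsr: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ws < 1:
            raise ValueError("ws must be >= 1")
        if not 0.0 < self.nsr <= 1.0:
            raise ValueError("nsr must be in (0, 1]")

    @property
    def negatives_per_center(self) -> int:
        """ceil((2*ws + 1) * nsr): 2 at the default ws=3, nsr=0.2."""
        return math.ceil((2 * self.ws + 1) * self.nsr)


@dataclass(frozen=True)
class SkipGramTuple:
    center: int
    partner: int
    label: int

    def __post_init__(self) -> None:
        if not (0 <= self.center < DICTIONARY_SIZE and 0 <= self.partner < DICTIONARY_SIZE):
            raise ValueError("switch indices must be in 0..639")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class EmbeddingConfig:
    embedding_length: int = 300
    epochs: int = 200
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_length < 1 or self.epochs < 1:
            raise ValueError("embedding_length and epochs must be >= 1")


@dataclass
class EmbeddingMatrix:
    """640 x L matrix of codon-switch vectors with provenance tags."""

    values: np.ndarray
    chromosome_tag: str = ""
    dict_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != DICTIONARY_SIZE:
            raise ValueError(f"embedding matrix must be ({DICTIONARY_SIZE}, L)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix has non-finite entries")

    @property
    def L(self) -> int:
        return self.values.shape[1]


def n_trainable_parameters(L: int = 300) -> int:
    """Parameter count of the embedding network: 640*L + w + b."""
    return DICTIONARY_SIZE * L + 2


def switch_frequencies(corpus: Sequence[CodonSwitchSequence]) -> np.ndarray:
    """Relative frequency of each switch index over all corpus occurrences."""
    if not corpus:
        raise ValueError("empty corpus")
    counts = np.zeros(DICTIONARY_SIZE, dtype=float)
    for seq in corpus:
        counts += np.bincount(seq.switch_indices, minlength=DICTIONARY_SIZE)
    total = counts.sum()
    if total == 0:
        raise ValueError("corpus contains no switches")
    return counts / total


def keep_probability(f: float, params: SubsamplingParams = SubsamplingParams()) -> float:
    """Center-subsampling keep probability min(1, sqrt(1 + f/eps)*eps/f).

    Rare switches (f <= eps, and f = 0 by limit) are always kept; frequent
    ones are kept with probability falling roughly like sqrt(eps/f).
    """
    if f < 0:
        raise ValueError("frequency must be nonnegative")
    if f == 0:
        return 1.0
    eps = params.epsilon
    return min(1.0, math.sqrt(1.0 + f / eps) * eps / f)


def select_centers(
    seq: CodonSwitchSequence,
    freqs: np.ndarray,
    params: SubsamplingParams,
    rng: np.random.Generator,
) -> list[int]:
    """Retain each position independently with its switch's keep probability."""
    keep = np.array([keep_probability(freqs[i], params) for i in seq.switch_indices])
    draws = rng.random(len(seq))
    return list(np.nonzero(draws < keep)[0])


def make_tuples(
    seq: CodonSwitchSequence,
    centers: Iterable[int],
    cfg: TupleGenConfig,
    rng: np.random.Generator,
) -> list[SkipGramTuple]:
    """Window positives plus uniform negatives for each selected center.

    An interior center yields 2*ws positives; centers near a sequence end
    see only the window positions that exist.  Negatives are drawn uniformly
    from the whole dictionary (collisions with true context switches are not
    excluded).
    """
    idx = seq.switch_indices
    n = len(idx)
    n_neg = cfg.negatives_per_center
    out: list[SkipGramTuple] = []
    for c in centers:
        if not 0 <= c < n:
            raise IndexError(f"center {c} outside sequence of length {n}")
        lo = max(0, c - cfg.ws)
        hi = min(n - 1, c + cfg.ws)
        for j in range(lo, hi + 1):
            if j != c:
                out.append(SkipGramTuple(idx[c], idx[j], 1))
        for partner in rng.integers(0, DICTIONARY_SIZE, size=n_neg):
            out.append(SkipGramTuple(idx[c], int(partner), 0))
    return out


def corpus_tuples(
    corpus: Sequence[CodonSwitchSequence],
    cfg: TupleGenConfig,
    params: SubsamplingParams = SubsamplingParams(),
) -> list[SkipGramTuple]:
    """Subsample centers and build tuples over a whole corpus (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    freqs = switch_frequencies(corpus)
    out: list[SkipGramTuple] = []
    for seq in corpus:
        centers = select_centers(seq, freqs, params, rng)
        out.extend(make_tuples(seq, centers, cfg, rng))
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def pair_logits(E: np.ndarray, w: float, b: float, centers, partners) -> np.ndarray:
    """Model logits w * <e_c, e_p> + b for tuple arrays."""
    dots = np.einsum("ij,ij->i", E[centers], E[partners])
    return w * dots + b


def bce_loss_and_grads(E, w, b, centers, partners, labels):
    """Binary cross-entropy and analytic gradients for a tuple batch.

    Returns (mean loss, dE, dw, db); the shared matrix receives gradient
    contributions from both the center and the partner role.
    """
    centers = np.asarray(centers)
    partners = np.asarray(partners)
    y = np.asarray(labels, dtype=float)
    dots = np.einsum("ij,ij->i", E[centers], E[partners])
    z = w * dots + b
    p = _sigmoid(z)
    # numerically stable BCE via logits
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (p - y) / len(y)
    dw = float(np.dot(dz, dots))
    db = float(dz.sum())
    dE = np.zeros_like(E)
    np.add.at(dE, centers, (w * dz)[:, None] * E[partners])
    np.add.at(dE, partners, (w * dz)[:, None] * E[centers])
    return float(loss), dE, dw, db


def train_embeddings(
    tuples: Sequence[SkipGramTuple],
    cfg: EmbeddingConfig,
    chromosome_tag: str = "",
    dict_fingerprint: str = "",
    loss_history: Optional[list] = None,
) -> EmbeddingMatrix:
    """Train the shared embedding matrix on labelled skip-gram tuples."""
    if not tuples:
        raise ValueError("empty tuple set")
    centers = np.array([t.center for t in tuples])
    partners = np.array([t.partner for t in tuples])
    labels = np.array([t.label for t in tuples], dtype=float)

    rng = np.random.default_rng(cfg.seed)
    L = cfg.embedding_length
    E = rng.uniform(-0.5, 0.5, size=(DICTIONARY_SIZE, L)) / L
    w, b = 1.0, 0.0

    # ADAM state for (E, w, b)
    mE = np.zeros_like(E)
    vE = np.zeros_like(E)
    mw = vw = mb = vb = 0.0
    t = 0
    n = len(tuples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sl = order[start : start + cfg.batch_size]
            loss, dE, dw, db = bce_loss_and_grads(
                E, w, b, centers[sl], partners[sl], labels[sl]
            )
            epoch_loss += loss * len(sl)
            t += 1
            lr = cfg.learning_rate * math.sqrt(1 - cfg.beta2**t) / (1 - cfg.beta1**t)
            mE = cfg.beta1 * mE + (1 - cfg.beta1) * dE
            vE = cfg.beta2 * vE + (1 - cfg.beta2) * dE**2
            E -= lr * mE / (np.sqrt(vE) + cfg.adam_eps)
            mw = cfg.beta1 * mw + (1 - cfg.beta1) * dw
            vw = cfg.beta2 * vw + (1 - cfg.beta2) * dw**2
            w -= lr * mw / (math.sqrt(vw) + cfg.adam_eps)
            mb = cfg.beta1 * mb + (1 - cfg.beta1) * db
            vb = cfg.beta2 * vb + (1 - cfg.beta2) * db**2
            b -= lr * mb / (math.sqrt(vb) + cfg.adam_eps)
        if loss_history is not None:
            loss_history.append(epoch_loss / n)
    return EmbeddingMatrix(E, chromosome_tag=chromosome_tag, dict_fingerprint=dict_fingerprint)
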