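"""Amino-acid n-gram profiles for cross-chromosome comparison.

CDS sequences are translated (stop codons included as a 21st symbol) and
summarised as unigram / bigram / trigram frequency vectors over the
21-letter alphabet (dimensions 21, 441 and 9261).  N-grams are counted with
overlap (stride 1) within each protein and never across protein boundaries.
Chromosomes are compared by the Spearman rank correlation of their
profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats as sps

from .dictionary import BASES, STOP_SYMBOL

__all__ = [
    "AA_ALPHABET",
    "NgramProfile",
    "translate_cds",
    "ngram_frequencies",
    "spearman_matrix",
]

#: 20 amino acids plus the stop symbol: 21 unigrams, 441 bigrams, 9261 trigrams.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + STOP_SYMBOL
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass
class NgramProfile:
    n: int
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if self.n not in (1, 2, 3):
            raise ValueError("n must be 1, 2 or 3")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        dim = len(AA_ALPHABET) ** self.n
        if self.frequencies.shape != (dim,):
            raise ValueError(f"profile for n={self.n} must have dimension {dim}")

    @staticmethod
    def labels(n: int) -> list[str]:
        return ["".join(t) for t in itertools.product(AA_ALPHABET, repeat=n)]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code; stops become '*'."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - set(BASES)
    if bad:
        raise ValueError(f"ambiguous or invalid bases in CDS: {sorted(bad)}")
    return str(Seq(cds).translate())


def ngram_frequencies(proteins: Sequence[str], n: int) -> NgramProfile:
    """Overlapping n-gram frequencies over a collection of proteins."""
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    base = len(AA_ALPHABET)
    counts = np.zeros(base**n, dtype=float)
    total = 0
    for prot in proteins:
        for i in range(len(prot) - n + 1):
            gram = prot[i : i + n]
            idx = 0
            for ch in gram:
                idx = idx * base + _AA_INDEX[ch]
            counts[idx] += 1
            total += 1
    if total == 0:
        raise ValueError(f"no {n}-grams: all proteins shorter than {n}")
    return NgramProfile(n, counts / total)


def spearman_matrix(profiles: Mapping[str, NgramProfile]) -> "pd.DataFrame":
    """Pairwise Spearman correlation of equally-sized n-gram profiles."""
    import pandas as pd

    names = list(profiles)
    if len(names) < 2:
        raise ValueError("need at least two profiles")
    ns = {profiles[k].n for k in names}
    if len(ns) > 1:
        raise ValueError("profiles have mismatched n")
    mat = np.vstack([profiles[k].frequencies for k in names])
    rho, _ = sps.spearmanr(mat, axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)
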