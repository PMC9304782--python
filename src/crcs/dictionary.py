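"""The codon-switch vocabulary.

A *codon switch* is a directional pair of codons — a reference codon and an
alternative codon — differing in at most one base.  With 64 codons and, for
each codon, 9 single-base neighbours (3 positions x 3 replacement bases) plus
the identity pair, the vocabulary has exactly 64 + 9*64 = 640 entries.  Every
protein-coding sequence, with or without a single-nucleotide variant, can be
rendered as a sequence over this vocabulary.

The dictionary ordering is canonical and deterministic: reference codons in
lexicographic order (AAA..TTT); within a reference codon the identity switch
first, then substitutions ordered by codon position (0, 1, 2) and then by
alternative base (A < C < G < T).  Index arithmetic is therefore closed-form:
each reference codon owns a block of ten consecutive indices.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from typing import Iterator

from Bio.Seq import Seq

BASES = "ACGT"
#: Translation symbol used for stop codons throughout the package.
STOP_SYMBOL = "*"

#: All 64 codons in lexicographic order.
CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: Number of switches in the vocabulary: 64 identities + 576 substitutions.
DICTIONARY_SIZE = 640
#: Switches per reference-codon block (1 identity + 9 substitutions).
BLOCK_SIZE = 10


class InvalidSwitchError(ValueError):
    """Raised for codon pairs at Hamming distance greater than one."""


def is_codon(s: str) -> bool:
    return len(s) == 3 and all(b in BASES for b in s)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) for *codon*; ``*`` for stop codons."""
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class CodonSwitch:
    """Directional codon pair (reference -> alternative), distance 0 or 1."""

    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not (is_codon(self.ref) and is_codon(self.alt)):
            raise InvalidSwitchError(f"not codons: {self.ref!r}->{self.alt!r}")
        if hamming(self.ref, self.alt) > 1:
            raise InvalidSwitchError(
                f"codon pair {self.ref}->{self.alt} differs at more than one base"
            )

    @property
    def is_identity(self) -> bool:
        return self.ref == self.alt

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.ref}>{self.alt}"


def classify_switch(cs: CodonSwitch) -> str:
    """Classify a switch as identity / synonymous / missense / nonsense.

    Nonsense means a non-stop codon switching to a stop codon.  A stop codon
    switching to a coding codon (stop-loss) is grouped with missense.
    """
    if cs.is_identity:
        return "identity"
    aa_ref = translate_codon(cs.ref)
    aa_alt = translate_codon(cs.alt)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == STOP_SYMBOL and aa_ref != STOP_SYMBOL:
        return "nonsense"
    return "missense"


class SwitchDictionary:
    """The 640-entry codon-switch vocabulary with its index bijection."""

    def __init__(self) -> None:
        entries: list[CodonSwitch] = []
        for ref in CODONS:
            entries.append(CodonSwitch(ref, ref))
            for pos in range(3):
                for base in BASES:
                    if base == ref[pos]:
                        continue
                    alt = ref[:pos] + base + ref[pos + 1 :]
                    entries.append(CodonSwitch(ref, alt))
        self.entries: tuple[CodonSwitch, ...] = tuple(entries)
        self.index_map: dict[CodonSwitch, int] = {
            cs: i for i, cs in enumerate(self.entries)
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CodonSwitch]:
        return iter(self.entries)

    def switch_index(self, cs: CodonSwitch) -> int:
        """Index of *cs* in 0..639 (raises for invalid pairs)."""
        try:
            return self.index_map[cs]
        except KeyError:
            raise InvalidSwitchError(f"{cs} not in dictionary") from None

    def index_of(self, ref: str, alt: str) -> int:
        return self.switch_index(CodonSwitch(ref, alt))

    def switch_of(self, index: int) -> CodonSwitch:
        if not 0 <= index < len(self.entries):
            raise IndexError(f"switch index {index} out of range 0..639")
        return self.entries[index]

    def identity_index(self, codon: str) -> int:
        """Index of the identity switch for *codon* (block head)."""
        return CODON_INDEX[codon] * BLOCK_SIZE

    @property
    def fingerprint(self) -> str:
        """Stable hash of the entry ordering, stamped onto embedding files."""
        payload = "|".join(f"{cs.ref}>{cs.alt}" for cs in self.entries)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_switch_dictionary() -> SwitchDictionary:
    """Build the canonical 640-entry codon-switch dictionary."""
    return SwitchDictionary()
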