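"""Gene models, variants, and codon-switch sequence construction.

Coordinates follow the conventions of the source formats: variants are
1-based (VCF), CDS exon intervals are 0-based half-open (BED).  Codons are
defined in spliced transcript space, so a codon spanning an exon junction is
handled naturally; minus-strand transcripts are reverse-complemented before
codon framing, and the variant's alternative base is complemented with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .dictionary import BASES, SwitchDictionary

__all__ = [
    "GeneModel",
    "Variant",
    "CodonSwitchSequence",
    "MalformedModelError",
    "CoordinateError",
    "NotCodingError",
    "RefMismatchError",
    "spliced_cds",
    "encode_variant",
    "map_to_transcripts",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MalformedModelError(ValueError):
    """Gene model violates its structural invariants (e.g. CDS % 3 != 0)."""


class CoordinateError(ValueError):
    """Interval or position outside the reference sequence."""


class NotCodingError(ValueError):
    """Variant does not fall inside the transcript's CDS."""


class RefMismatchError(ValueError):
    """Variant REF base disagrees with the reference genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding transcript: strand plus ordered CDS exon intervals."""

    transcript_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise MalformedModelError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.cds_exons)
        object.__setattr__(self, "cds_exons", exons)
        prev_end = -1
        for start, end in exons:
            if not (0 <= start < end):
                raise MalformedModelError(f"bad interval ({start}, {end})")
            if start < prev_end:
                raise MalformedModelError("CDS exons overlap or are unsorted")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise MalformedModelError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_exons)

    def contains(self, position: int) -> bool:
        """True if the 1-based genomic *position* lies in the CDS."""
        p = position - 1
        return any(start <= p < end for start, end in self.cds_exons)

    def cds_offset(self, position: int) -> int:
        """Spliced CDS index (0-based, transcript orientation) of *position*."""
        p = position - 1
        offset = 0
        for start, end in self.cds_exons:
            if start <= p < end:
                plus_offset = offset + (p - start)
                if self.strand == "+":
                    return plus_offset
                return self.cds_length - 1 - plus_offset
            offset += end - start
        raise NotCodingError(
            f"position {position} not in CDS of {self.transcript_id}"
        )


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant on the genomic plus strand (1-based POS)."""

    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    source_label: str = ""
    pathogenicity_flag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError(
                f"ref/alt must be single bases in ACGT: {self.ref_base!r}/{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt bases are identical")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref_base, self.alt_base)


@dataclass
class CodonSwitchSequence:
    """A transcript CDS rendered as switch indices.

    All switches are identities except (at most) the single codon carrying
    the variant.
    """

    transcript_id: str
    switch_indices: list[int]
    variant_codon_offset: Optional[int] = None
    variant_key: Optional[tuple[str, int, str, str]] = None
    label: Optional[int] = None
    gene_symbol: str = ""

    def __len__(self) -> int:
        return len(self.switch_indices)

    def with_label(self, label: int) -> "CodonSwitchSequence":
        return replace(self, label=label)


def spliced_cds(gm: GeneModel, ref: Mapping[str, str]) -> str:
    """Extract the spliced CDS of *gm* in transcript orientation."""
    try:
        chrom = ref[gm.chromosome]
    except KeyError:
        raise CoordinateError(f"chromosome {gm.chromosome!r} not in reference") from None
    parts = []
    for start, end in gm.cds_exons:
        if end > len(chrom):
            raise CoordinateError(
                f"{gm.transcript_id}: interval ({start}, {end}) beyond chromosome end"
            )
        parts.append(chrom[start:end])
    cds = "".join(parts)
    if gm.strand == "-":
        cds = reverse_complement(cds)
    return cds


def encode_variant(
    v: Variant,
    gm: GeneModel,
    ref: Mapping[str, str],
    dictionary: SwitchDictionary,
) -> CodonSwitchSequence:
    """Render *v* on transcript *gm* as a codon-switch sequence.

    Every codon maps to its identity switch except the codon containing the
    variant, which maps to (reference codon -> codon with the
    transcript-oriented alternative base substituted).
    """
    if v.chromosome != gm.chromosome:
        raise NotCodingError(f"variant on {v.chromosome}, model on {gm.chromosome}")
    if not gm.contains(v.position):
        raise NotCodingError(
            f"position {v.position} outside CDS of {gm.transcript_id}"
        )
    genome_base = ref[gm.chromosome][v.position - 1]
    if genome_base != v.ref_base:
        raise RefMismatchError(
            f"{v.chromosome}:{v.position} reference is {genome_base}, variant says {v.ref_base}"
        )
    cds = spliced_cds(gm, ref)
    cds_idx = gm.cds_offset(v.position)
    alt = v.alt_base if gm.strand == "+" else reverse_complement(v.alt_base)

    codon_offset = cds_idx // 3
    within = cds_idx % 3
    indices = [
        dictionary.identity_index(cds[i : i + 3]) for i in range(0, len(cds), 3)
    ]
    ref_codon = cds[codon_offset * 3 : codon_offset * 3 + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    indices[codon_offset] = dictionary.index_of(ref_codon, alt_codon)
    return CodonSwitchSequence(
        transcript_id=gm.transcript_id,
        switch_indices=indices,
        variant_codon_offset=codon_offset,
        variant_key=v.key,
        gene_symbol=gm.gene_symbol,
    )


def encode_reference(
    gm: GeneModel, ref: Mapping[str, str], dictionary: SwitchDictionary
) -> CodonSwitchSequence:
    """All-identity switch sequence of a transcript without any variant."""
    cds = spliced_cds(gm, ref)
    indices = [
        dictionary.identity_index(cds[i : i + 3]) for i in range(0, len(cds), 3)
    ]
    return CodonSwitchSequence(
        transcript_id=gm.transcript_id,
        switch_indices=indices,
        gene_symbol=gm.gene_symbol,
    )


def map_to_transcripts(
    v: Variant,
    models: Sequence[GeneModel],
    ref: Mapping[str, str],
    dictionary: SwitchDictionary,
) -> list[CodonSwitchSequence]:
    """Encode *v* on every transcript whose CDS contains it."""
    out = []
    for gm in models:
        if gm.chromosome != v.chromosome or not gm.contains(v.position):
            continue
        out.append(encode_variant(v, gm, ref, dictionary))
    return out
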