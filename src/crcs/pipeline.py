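"""Variant pruning pipeline.

Mirrors the preprocessing applied to population and tumor variant calls
before embedding and classification: restrict to single-nucleotide variants,
keep only variants that land in a CDS (inflating by splice variants), drop
duplicates on a transcript-level key, drop synonymous switches, drop records
flagged pathogenic, and optionally hold out a fraction of variants for
embedding training, disjoint from the classification set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dictionary import BASES, SwitchDictionary, classify_switch
from .models import CodonSwitchSequence, GeneModel, Variant, map_to_transcripts

__all__ = [
    "RawVariantRecord",
    "FilterConfig",
    "FilterResult",
    "ConfigError",
    "variant_filter_pipeline",
    "DEFAULT_STAGES",
]

DEFAULT_STAGES = (
    "snv_only",
    "coding_only",
    "dedupe",
    "drop_synonymous",
    "drop_pathogenic",
    "embedding_split",
)


class ConfigError(ValueError):
    """Unknown stage name or invalid pipeline configuration."""


@dataclass(frozen=True)
class RawVariantRecord:
    """An unfiltered variant call; ref/alt may be multi-base (indels)."""

    chromosome: str
    position: int
    ref: str
    alt: str
    source_label: str = ""
    pathogenicity_flag: Optional[str] = None

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in BASES
            and self.alt in BASES
            and self.ref != self.alt
        )


@dataclass
class FilterConfig:
    stages: Sequence[str] = DEFAULT_STAGES
    embedding_fraction: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown pipeline stage(s): {sorted(unknown)}")
        if not 0.0 <= self.embedding_fraction < 1.0:
            raise ConfigError("embedding_fraction must be in [0, 1)")


@dataclass
class FilterResult:
    """Retained records plus per-stage bookkeeping.

    ``classification`` and ``embedding`` are (variant, sequence) record lists;
    the embedding hold-out is disjoint from the classification set at the
    variant level.
    """

    classification: list[tuple[Variant, CodonSwitchSequence]]
    embedding: list[tuple[Variant, CodonSwitchSequence]]
    stage_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def retained_variants(self) -> list[Variant]:
        seen: dict[tuple, Variant] = {}
        for v, _ in self.classification:
            seen.setdefault(v.key, v)
        return list(seen.values())

    @property
    def sequences(self) -> list[CodonSwitchSequence]:
        return [s for _, s in self.classification]


def _as_raw(rec) -> RawVariantRecord:
    if isinstance(rec, RawVariantRecord):
        return rec
    if isinstance(rec, Variant):
        return RawVariantRecord(
            rec.chromosome,
            rec.position,
            rec.ref_base,
            rec.alt_base,
            rec.source_label,
            rec.pathogenicity_flag,
        )
    raise TypeError(f"cannot interpret {rec!r} as a variant record")


def variant_filter_pipeline(
    records: Sequence,
    models: Sequence[GeneModel],
    ref: Mapping[str, str],
    dictionary: SwitchDictionary,
    config: Optional[FilterConfig] = None,
) -> FilterResult:
    """Apply the configured pruning stages in order.

    Each stage's output is a subset of its input; ``stage_counts`` maps the
    stage name to (records in, records out).  Counts before ``coding_only``
    are variant records; from ``coding_only`` on they are (variant,
    transcript) records, inflated by splice mapping.
    """
    config = config or FilterConfig()
    counts: dict[str, tuple[int, int]] = {}

    raw = [_as_raw(r) for r in records]
    variants: list[Variant] = []
    pairs: list[tuple[Variant, CodonSwitchSequence]] = []
    mapped = False

    for stage in config.stages:
        if stage == "snv_only":
            n_in = len(variants) if mapped else len(raw)
            raw = [r for r in raw if r.is_snv]
            counts[stage] = (n_in, len(raw))
        elif stage == "coding_only":
            variants = [
                Variant(
                    r.chromosome,
                    r.position,
                    r.ref,
                    r.alt,
                    r.source_label,
                    r.pathogenicity_flag,
                )
                for r in raw
                if r.is_snv
            ]
            pairs = []
            for v in variants:
                for seq in map_to_transcripts(v, models, ref, dictionary):
                    pairs.append((v, seq))
            counts[stage] = (len(variants), len(pairs))
            mapped = True
        elif stage == "dedupe":
            n_in = len(pairs)
            seen: set[tuple] = set()
            kept = []
            for v, seq in pairs:
                off = seq.variant_codon_offset
                key = (seq.transcript_id, off, seq.switch_indices[off])
                if key in seen:
                    continue
                seen.add(key)
                kept.append((v, seq))
            pairs = kept
            counts[stage] = (n_in, len(pairs))
        elif stage == "drop_synonymous":
            n_in = len(pairs)
            kept = []
            for v, seq in pairs:
                cs = dictionary.switch_of(
                    seq.switch_indices[seq.variant_codon_offset]
                )
                if classify_switch(cs) != "synonymous":
                    kept.append((v, seq))
            pairs = kept
            counts[stage] = (n_in, len(pairs))
        elif stage == "drop_pathogenic":
            n_in = len(pairs)
            pairs = [
                (v, seq)
                for v, seq in pairs
                if not (
                    v.pathogenicity_flag
                    and "pathogenic" in v.pathogenicity_flag.lower()
                )
            ]
            counts[stage] = (n_in, len(pairs))
        elif stage == "embedding_split":
            n_in = len(pairs)
            keys = sorted({v.key for v, _ in pairs})
            rng = np.random.default_rng(config.seed)
            rng.shuffle(keys)
            n_emb = int(round(config.embedding_fraction * len(keys)))
            emb_keys = set(keys[:n_emb])
            embedding = [(v, s) for v, s in pairs if v.key in emb_keys]
            pairs = [(v, s) for v, s in pairs if v.key not in emb_keys]
            counts[stage] = (n_in, len(pairs))
            return FilterResult(pairs, embedding, counts)
        else:  # pragma: no cover - guarded by FilterConfig
            raise ConfigError(f"unknown stage {stage!r}")

    return FilterResult(pairs, [], counts)
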