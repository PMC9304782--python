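"""Seeded synthetic genomes, variant classes and survival cohorts.

The generator emulates the statistical structure the rest of the toolkit
assumes:

* a toy multi-gene, multi-exon, two-strand genome whose CDSs are random
  sense codons (GC content tunable);
* two variant classes whose *flanking* codon composition differs: each gene
  is partitioned into disjoint planting slots of 2*ws+1 codons, every
  variant owns one slot, and with probability beta the 2*ws codons flanking
  the variant codon are redrawn from a class-conditional codon distribution
  (background otherwise).  At beta = 0 the classes are indistinguishable by
  construction; the mixture weight beta parameterises task difficulty.
  Genes are assigned to a single class so the planted composition signal is
  coherent within each reference CDS;
* survival cohorts whose exponential hazard scales like exp(gamma * s) in
  the patient's cumulative mutation score s, with independent censoring.

All generators are pure functions of (config, seed) and replay exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dictionary import BASES, CODONS, SwitchDictionary, classify_switch, CodonSwitch
from .models import (
    CodonSwitchSequence,
    GeneModel,
    Variant,
    encode_variant,
    reverse_complement,
    spliced_cds,
)
from .survival import PatientProfile, blacs_score

__all__ = [
    "GenomeSimConfig",
    "VariantSimConfig",
    "SurvivalSimConfig",
    "VariantSimResult",
    "simulate_genome",
    "simulate_variants",
    "simulate_survival",
    "simulate_survival_cohort",
    "encode_variant_sets",
]

#: Codons that do not translate to stop; CDS interiors are built from these.
SENSE_CODONS = [c for c in CODONS if c not in ("TAA", "TAG", "TGA")]


class SimConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class GenomeSimConfig:
    n_chromosomes: int = 2
    n_genes: int = 50
    exon_count_range: tuple[int, int] = (1, 3)
    codons_range: tuple[int, int] = (40, 63)
    intron_range: tuple[int, int] = (20, 60)
    intergenic_range: tuple[int, int] = (30, 80)
    gc_content: float = 0.5
    minus_strand_prob: float = 0.5
    max_chromosome_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise SimConfigError("need at least one chromosome and one gene")
        if self.codons_range[0] < 3 or self.codons_range[0] > self.codons_range[1]:
            raise SimConfigError("invalid codons_range")
        if self.exon_count_range[0] < 1:
            raise SimConfigError("exon count must be >= 1")
        if not 0.0 < self.gc_content < 1.0:
            raise SimConfigError("gc_content must be in (0, 1)")
        for lo, hi in (self.intron_range, self.intergenic_range):
            if lo < 1 or lo > hi:
                raise SimConfigError("length ranges must be positive and ordered")


def _codon_background(gc: float) -> np.ndarray:
    pb = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in SENSE_CODONS])
    return w / w.sum()


def simulate_genome(
    cfg: GenomeSimConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Build a toy reference with multi-exon gene models on both strands."""
    rng = np.random.default_rng(cfg.seed)
    probs = _codon_background(cfg.gc_content)
    chrom_parts: dict[str, list[str]] = {
        f"chrS{i + 1}": [] for i in range(cfg.n_chromosomes)
    }
    chrom_pos = {name: 0 for name in chrom_parts}
    models: list[GeneModel] = []

    def random_seq(n: int) -> str:
        p = np.array(
            [(1 - cfg.gc_content) / 2, cfg.gc_content / 2, cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
        )
        return "".join(rng.choice(list("ACGT"), size=n, p=p / p.sum()))

    for g in range(cfg.n_genes):
        chrom = f"chrS{g % cfg.n_chromosomes + 1}"
        n_codons = int(rng.integers(cfg.codons_range[0], cfg.codons_range[1] + 1))
        cds = "".join(
            SENSE_CODONS[i]
            for i in rng.choice(len(SENSE_CODONS), size=n_codons, p=probs)
        )
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        # force both strands once there are two or more genes
        if cfg.n_genes >= 2 and g < 2:
            strand = "+-"[g]
        genomic_cds = cds if strand == "+" else reverse_complement(cds)
        n_exons = int(
            rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1)
        )
        n_exons = min(n_exons, len(genomic_cds))
        # split the genomic CDS at arbitrary nucleotide boundaries so codons
        # may span exon junctions
        if n_exons > 1:
            cutpoints = sorted(
                rng.choice(np.arange(1, len(genomic_cds)), size=n_exons - 1, replace=False)
            )
        else:
            cutpoints = []
        bounds = [0, *cutpoints, len(genomic_cds)]
        # lay out on the chromosome
        gap = int(rng.integers(cfg.intergenic_range[0], cfg.intergenic_range[1] + 1))
        chrom_parts[chrom].append(random_seq(gap))
        pos = chrom_pos[chrom] + gap
        exons = []
        for i in range(n_exons):
            piece = genomic_cds[bounds[i] : bounds[i + 1]]
            exons.append((pos, pos + len(piece)))
            chrom_parts[chrom].append(piece)
            pos += len(piece)
            if i < n_exons - 1:
                intron = int(rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1))
                chrom_parts[chrom].append(random_seq(intron))
                pos += intron
        chrom_pos[chrom] = pos
        gene_id = f"G{g:04d}"
        models.append(
            GeneModel(
                transcript_id=f"{gene_id}.t1",
                gene_symbol=gene_id,
                chromosome=chrom,
                strand=strand,
                cds_exons=tuple(exons),
            )
        )
    ref = {}
    for name, parts in chrom_parts.items():
        tail = int(np.random.default_rng(cfg.seed + 1).integers(20, 40))
        seq = "".join(parts) + "A" * tail
        if cfg.max_chromosome_length is not None and len(seq) > cfg.max_chromosome_length:
            raise SimConfigError(
                f"{name}: assembled length {len(seq)} exceeds max_chromosome_length"
            )
        ref[name] = seq
    return ref, models


@dataclass
class VariantSimConfig:
    n_per_class: int = 400
    beta: float = 0.5
    ws: int = 3
    class0_codons: tuple[str, ...] = ()
    class1_codons: tuple[str, ...] = ()
    gc_content: float = 0.5
    ensure_nonsynonymous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise SimConfigError("beta must be in [0, 1]")
        if self.n_per_class < 1 or self.ws < 1:
            raise SimConfigError("n_per_class and ws must be >= 1")
        if not self.class0_codons:
            self.class0_codons = tuple(c for c in SENSE_CODONS if c[0] in "AT")
        if not self.class1_codons:
            self.class1_codons = tuple(c for c in SENSE_CODONS if c[0] in "GC")


@dataclass
class VariantSimResult:
    """Planted variant classes plus the (rewritten) reference."""

    reference: dict[str, str]
    variants: list[Variant]
    labels: dict[tuple, int]
    gene_class: dict[str, int]

    def by_class(self, label: int) -> list[Variant]:
        return [v for v in self.variants if self.labels[v.key] == label]


def _transcript_positions(gm: GeneModel) -> list[int]:
    """Genomic position (0-based) of each transcript-space nucleotide."""
    plus = [p for start, end in gm.cds_exons for p in range(start, end)]
    return plus if gm.strand == "+" else plus[::-1]


def simulate_variants(
    ref: dict[str, str],
    models: Sequence[GeneModel],
    cfg: VariantSimConfig,
) -> VariantSimResult:
    """Plant two variant classes with class-conditional flanking contexts.

    Returns a result whose ``reference`` carries the planted context
    windows; downstream encoding must use that reference, not the input
    one.  Class labels: 0 = population-like, 1 = cancer-like.
    """
    if not models:
        raise SimConfigError("no gene models supplied")
    rng = np.random.default_rng(cfg.seed)
    window = 2 * cfg.ws + 1
    mutable = {name: list(seq) for name, seq in ref.items()}

    # slot bookkeeping per gene
    gene_slots: dict[str, list[int]] = {}
    capacity = 0
    for gm in models:
        n_slots = (gm.cds_length // 3) // window
        gene_slots[gm.transcript_id] = list(range(n_slots))
        capacity += n_slots
    if capacity < 2 * cfg.n_per_class:
        raise SimConfigError(
            f"not enough eligible coding positions: {capacity} slots for "
            f"{2 * cfg.n_per_class} variants"
        )

    order = list(models)
    rng.shuffle(order)
    # assign genes to classes greedily (larger capacity to the class that
    # has less) so both classes can host n_per_class variants
    gene_class: dict[str, int] = {}
    cap = {0: 0, 1: 0}
    for gm in sorted(order, key=lambda g: -len(gene_slots[g.transcript_id])):
        label = 0 if cap[0] <= cap[1] else 1
        gene_class[gm.gene_symbol] = label
        cap[label] += len(gene_slots[gm.transcript_id])
    class_pool = {0: cfg.class0_codons, 1: cfg.class1_codons}

    variants: list[Variant] = []
    labels: dict[tuple, int] = {}
    counts = {0: 0, 1: 0}
    for gm in order:
        label = gene_class[gm.gene_symbol]
        if counts[label] >= cfg.n_per_class:
            continue
        tpos = _transcript_positions(gm)
        cds = spliced_cds(gm, {k: "".join(v) for k, v in mutable.items()})
        slots = gene_slots[gm.transcript_id]
        rng.shuffle(slots)
        for slot in slots:
            if counts[label] >= cfg.n_per_class:
                break
            first_codon = slot * window
            center_codon = first_codon + cfg.ws

            def write_codon(codon_idx: int, codon: str) -> None:
                for k in range(3):
                    t = codon_idx * 3 + k
                    base = codon[k] if gm.strand == "+" else reverse_complement(codon[k])
                    mutable[gm.chromosome][tpos[t]] = base

            if rng.random() < cfg.beta:
                pool = class_pool[label]
                for ci in range(first_codon, first_codon + window):
                    if ci == center_codon:
                        continue
                    write_codon(ci, pool[int(rng.integers(len(pool)))])

            # place the SNV inside the (untouched) center codon
            ref_codon = cds[center_codon * 3 : center_codon * 3 + 3]
            choices = [
                (w, b)
                for w in range(3)
                for b in BASES
                if b != ref_codon[w]
            ]
            rng.shuffle(choices)
            chosen = None
            for w, b in choices:
                alt_codon = ref_codon[:w] + b + ref_codon[w + 1 :]
                kind = classify_switch(CodonSwitch(ref_codon, alt_codon))
                if not cfg.ensure_nonsynonymous or kind != "synonymous":
                    chosen = (w, b)
                    break
            if chosen is None:
                continue
            w, b = chosen
            t = center_codon * 3 + w
            gpos = tpos[t]
            ref_base = mutable[gm.chromosome][gpos]
            alt_base = b if gm.strand == "+" else reverse_complement(b)
            v = Variant(
                chromosome=gm.chromosome,
                position=gpos + 1,
                ref_base=ref_base,
                alt_base=alt_base,
                source_label="cancer" if label == 1 else "population",
            )
            if v.key in labels:
                continue
            variants.append(v)
            labels[v.key] = label
            counts[label] += 1
    if counts[0] < cfg.n_per_class or counts[1] < cfg.n_per_class:
        raise SimConfigError(
            f"could only place {counts[0]}/{counts[1]} variants per class"
        )
    reference = {name: "".join(chars) for name, chars in mutable.items()}
    return VariantSimResult(reference, variants, labels, gene_class)


def encode_variant_sets(
    result: VariantSimResult,
    models: Sequence[GeneModel],
    dictionary: SwitchDictionary,
) -> tuple[list[CodonSwitchSequence], np.ndarray]:
    """Encode planted variants against their (rewritten) reference."""
    model_ix: dict[str, list[GeneModel]] = {}
    for gm in models:
        model_ix.setdefault(gm.chromosome, []).append(gm)
    seqs = []
    labels = []
    for v in result.variants:
        for gm in model_ix.get(v.chromosome, []):
            if gm.contains(v.position):
                seq = encode_variant(v, gm, result.reference, dictionary)
                seq.label = result.labels[v.key]
                seqs.append(seq)
                labels.append(result.labels[v.key])
                break
    return seqs, np.asarray(labels, dtype=int)


@dataclass
class SurvivalSimConfig:
    n_patients: int = 150
    cancer_type: str = "SYN"
    mutations_range: tuple[int, int] = (5, 20)
    base_rate: float = 0.02
    gamma: float = 0.3
    censoring_rate: float = 0.2
    k: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise SimConfigError("base_rate must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise SimConfigError("censoring_rate must be in [0, 1)")
        if self.mutations_range[0] < 1:
            raise SimConfigError("patients need at least one mutation")


def simulate_survival(blacs_scores, cfg: SurvivalSimConfig) -> pd.DataFrame:
    """Survival table for given per-patient cumulative scores.

    Event times are exponential with rate base_rate * exp(gamma * score);
    a patient is independently censored with probability censoring_rate at
    a uniform fraction of the event time.
    """
    rng = np.random.default_rng(cfg.seed)
    scores = np.asarray(blacs_scores, dtype=float)
    rates = cfg.base_rate * np.exp(cfg.gamma * scores)
    times = rng.exponential(1.0 / rates)
    censored = rng.random(scores.size) < cfg.censoring_rate
    observed = np.where(censored, times * rng.random(scores.size), times)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(scores.size)],
            "cancer_type": cfg.cancer_type,
            "blacs_score": scores,
            "os_time": observed,
            "os_event": (~censored).astype(int),
        }
    )


def simulate_survival_cohort(cfg: SurvivalSimConfig) -> list[PatientProfile]:
    """Full synthetic cohort: per-mutation scores plus linked survival."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mutations_range
    n_mut = rng.integers(lo, hi + 1, size=cfg.n_patients)
    mutation_scores = [rng.random(int(n)).tolist() for n in n_mut]
    scores = np.array([blacs_score(s, cfg.k) for s in mutation_scores])
    table = simulate_survival(scores, replace(cfg, seed=cfg.seed + 1))
    return [
        PatientProfile(
            patient_id=row.patient_id,
            cancer_type=row.cancer_type,
            mutation_scores=mutation_scores[i],
            survival_time=float(row.os_time),
            event=int(row.os_event),
        )
        for i, row in enumerate(table.itertuples(index=False))
    ]
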