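"""Readers and writers for the formats the toolkit touches.

FASTA via Biopython; gene models from BED12 or a refGene-style tab table;
a minimal VCF subset (SNV records only, multi-allelic records decomposed);
tab-separated score, sequence and tuple tables; and the headered text format
for embedding matrices.  Readers reject structurally invalid input rather
than silently repairing it; skipped records are counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .models import GeneModel, MalformedModelError, Variant
from .pipeline import RawVariantRecord

logger = logging.getLogger("crcs")

__all__ = [
    "ParseError",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_vcf_snvs",
    "write_vcf",
    "write_scores",
    "read_scores",
    "write_sequences",
    "read_sequences",
    "write_embedding_matrix",
    "read_embedding_matrix",
]


class ParseError(ValueError):
    """Structurally invalid input file."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Flat run configuration; every stage parameter with its default.

    Defaults are the study conditions: skip-gram window ws=3, negative
    sampling rate nsr=0.2, subsampling floor epsilon=0.001, embedding length
    L=300, 200 epochs, 4 gene-disjoint folds, sequence length cap 1500,
    minimum 200 variants per gene, scoring threshold 0.9, survival scaling
    k=4, >=5 mutations per patient and >=100 patients per cancer type.
    """

    ws: int = 3
    nsr: float = 0.2
    epsilon: float = 0.001
    embedding_length: int = 300
    embedding_epochs: int = 200
    blac_epochs: int = 200
    folds: int = 4
    max_len: int = 1500
    min_gene_variants: int = 200
    threshold: float = 0.9
    k: float = 4.0
    min_mutations: int = 5
    min_patients_per_type: int = 100
    min_group_size: int = 5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ws < 1:
            raise ValueError("ws must be >= 1")
        if not 0 < self.nsr <= 1:
            raise ValueError("nsr must be in (0, 1]")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if self.embedding_length < 1 or self.folds < 2 or self.max_len < 1:
            raise ValueError("invalid configuration value")
        if self.k <= 0:
            raise ValueError("k must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercased sequence}."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ParseError(f"{path}: invalid characters {sorted(bad)} in {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models

_TAB_COLUMNS = [
    "transcript_id",
    "gene_symbol",
    "chromosome",
    "strand",
    "exon_starts",
    "exon_ends",
]


def _model_from_intervals(tid, gene, chrom, strand, starts, ends) -> GeneModel:
    exons = tuple(zip(starts, ends))
    return GeneModel(tid, gene, chrom, strand, exons)


def read_gene_models(path, dialect: str = "tab") -> list[GeneModel]:
    """Read gene models from BED12 or a refGene-style tab table.

    Models whose CDS length is not a multiple of three are skipped with a
    logged count, mirroring how malformed transcript annotations are pruned.
    """
    if dialect not in {"bed12", "tab"}:
        raise ParseError(f"unknown gene-model dialect {dialect!r}")
    models: list[GeneModel] = []
    skipped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        try:
            if dialect == "bed12":
                if len(cols) < 12:
                    raise ParseError(
                        f"{path}:{lineno}: BED12 needs 12 columns, got {len(cols)}"
                    )
                chrom, chrom_start = cols[0], int(cols[1])
                name, strand = cols[3], cols[5]
                thick_start, thick_end = int(cols[6]), int(cols[7])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
                if len(sizes) != int(cols[9]) or len(offsets) != int(cols[9]):
                    raise ParseError(f"{path}:{lineno}: block count mismatch")
                starts, ends = [], []
                for off, size in zip(offsets, sizes):
                    s = chrom_start + off
                    e = s + size
                    cs, ce = max(s, thick_start), min(e, thick_end)
                    if cs < ce:
                        starts.append(cs)
                        ends.append(ce)
                tid, _, gene = name.partition("|")
                model = _model_from_intervals(
                    tid, gene or tid, chrom, strand, starts, ends
                )
            else:
                if len(cols) != len(_TAB_COLUMNS):
                    raise ParseError(
                        f"{path}:{lineno}: expected {len(_TAB_COLUMNS)} columns, got {len(cols)}"
                    )
                tid, gene, chrom, strand, starts_s, ends_s = cols
                starts = [int(x) for x in starts_s.rstrip(",").split(",")]
                ends = [int(x) for x in ends_s.rstrip(",").split(",")]
                model = _model_from_intervals(tid, gene, chrom, strand, starts, ends)
        except MalformedModelError as exc:
            skipped += 1
            logger.warning("skipping gene model at %s:%d: %s", path, lineno, exc)
            continue
        models.append(model)
    if skipped:
        logger.info("read_gene_models: skipped %d malformed model(s)", skipped)
    return models


def write_gene_models(path, models) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TAB_COLUMNS) + "\n")
        for gm in models:
            starts = ",".join(str(s) for s, _ in gm.cds_exons)
            ends = ",".join(str(e) for _, e in gm.cds_exons)
            fh.write(
                "\t".join(
                    [gm.transcript_id, gm.gene_symbol, gm.chromosome, gm.strand, starts, ends]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF (minimal SNV subset)


def read_vcf_snvs(
    path,
    source_label: str = "",
    pathogenicity_info_key: str = "CLNSIG",
    keep_non_snv: bool = False,
):
    """Read SNV records from a VCF-like text file.

    Only records whose REF and ALT are single bases are returned as
    :class:`Variant`; multi-allelic records are decomposed into one variant
    per alternative allele.  Non-SNV records are skipped and counted (or, if
    *keep_non_snv*, returned as raw records for the filter pipeline).
    """
    variants: list[Variant] = []
    raws: list[RawVariantRecord] = []
    n_skipped = 0
    saw_data = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise ParseError(f"{path}:{lineno}: VCF records need >=5 columns")
        saw_data = True
        chrom, pos_s, _id, ref, alts = cols[:5]
        info = cols[7] if len(cols) >= 8 else ""
        flag = None
        for kv in info.split(";"):
            key, _, value = kv.partition("=")
            if key == pathogenicity_info_key and value:
                flag = value
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: POS is not an integer") from None
        for alt in alts.split(","):
            rec = RawVariantRecord(chrom, pos, ref, alt, source_label, flag)
            if rec.is_snv:
                variants.append(
                    Variant(chrom, pos, ref, alt, source_label, flag)
                )
            else:
                n_skipped += 1
            raws.append(rec)
    if not saw_data:
        raise ParseError(f"{path}: no VCF data lines found")
    if n_skipped:
        logger.info("read_vcf_snvs: skipped %d non-SNV allele(s)", n_skipped)
    if keep_non_snv:
        return raws
    return variants


def write_vcf(path, variants) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"SOURCE={v.source_label}" if v.source_label else "."
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.ref_base}\t{v.alt_base}\t.\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# score tables

_SCORE_COLUMNS = [
    "chromosome",
    "position",
    "ref",
    "alt",
    "transcript_id",
    "score",
    "label",
    "fold",
]


def write_scores(path, scored) -> None:
    """Write ScoredVariant records as a TSV; scores must lie in [0, 1]."""
    rows = []
    for sv in scored:
        if not 0.0 <= sv.score <= 1.0:
            raise ValueError(f"score {sv.score} outside [0, 1]")
        chrom, pos, ref, alt = sv.variant_key
        rows.append((chrom, pos, ref, alt, sv.transcript_id, sv.score, sv.label, sv.fold))
    df = pd.DataFrame(rows, columns=_SCORE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing score columns {sorted(missing)}")
    if len(df) and not df["score"].between(0, 1).all():
        raise ParseError(f"{path}: scores outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# codon switch sequence tables


def write_sequences(path, seqs) -> None:
    rows = []
    for s in seqs:
        key = s.variant_key or ("", -1, "", "")
        rows.append(
            (
                s.transcript_id,
                s.gene_symbol,
                f"{key[0]}:{key[1]}:{key[2]}:{key[3]}",
                -1 if s.variant_codon_offset is None else s.variant_codon_offset,
                ",".join(str(i) for i in s.switch_indices),
                "" if s.label is None else s.label,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_symbol", "variant_key", "offset", "switches", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_sequences(path):
    from .models import CodonSwitchSequence

    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "label": "Int64"})
    out = []
    for row in df.itertuples(index=False):
        chrom, pos, ref, alt = str(row.variant_key).split(":")
        key = None if pos == "-1" else (chrom, int(pos), ref, alt)
        out.append(
            CodonSwitchSequence(
                transcript_id=row.transcript_id,
                gene_symbol=row.gene_symbol,
                switch_indices=[int(x) for x in str(row.switches).split(",")],
                variant_codon_offset=None if row.offset < 0 else int(row.offset),
                variant_key=key,
                label=None if pd.isna(row.label) else int(row.label),
            )
        )
    return out


# ---------------------------------------------------------------------------
# embedding matrices


def write_embedding_matrix(path, emb) -> None:
    """Write an embedding matrix with its provenance header.

    Header lines record L, the chromosome tag and the dictionary-ordering
    fingerprint; row i of the body is the vector of switch index i.
    """
    header = (
        f"# L={emb.values.shape[1]}\n"
        f"# chromosome_tag={emb.chromosome_tag}\n"
        f"# dict_fingerprint={emb.dict_fingerprint}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, emb.values, fmt="%.10g", delimiter="\t")


def read_embedding_matrix(path):
    from .embedding import EmbeddingMatrix

    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
    values = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    if "L" not in meta or "dict_fingerprint" not in meta:
        raise ParseError(f"{path}: missing embedding header")
    if values.shape[1] != int(meta["L"]):
        raise ParseError(f"{path}: header L={meta['L']} but matrix has {values.shape[1]} columns")
    return EmbeddingMatrix(
        values=values,
        chromosome_tag=meta.get("chromosome_tag", ""),
        dict_fingerprint=meta["dict_fingerprint"],
    )
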