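"""Annotation curation: conversion of annotation-server plain-text tables,
union of two annotation sets, CDS validation with bounded rescue, and
gene-content summaries.

CDS validation checks each coding region for (a) a terminal initiator codon
{ATG, GTG, TTG} and stop codon {TAA, TAG, TGA}, (b) absence of internal
stops, and (c) a length that is a multiple of three.  A missing start or stop
is rescued by scanning up to ``rescue_window`` bp upstream/downstream
in frame for the nearest valid codon and extending the annotation; an ACG
start suggests RNA editing and is recorded as a feature exception rather
than extended away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from plastokit.seqio import (
    START_CODONS,
    STOP_CODONS,
    AnnotatedGenome,
    GenomeFeature,
    NucleotideSequence,
    gc_fraction,
)
from plastokit.assemblyfinish import QuadripartitePartition


# ---------------------------------------------------------------------------
# server-table parsing
# ---------------------------------------------------------------------------


@dataclass
class TableDialect:
    """Column layout of an annotation server's plain-text table.

    The default expects whitespace-delimited rows ``start end [strand] gene
    [kind]`` with 1-based inclusive coordinates; rows with end < start are
    read as minus-strand and normalized.
    """

    columns: tuple[str, ...] = ("start", "end", "strand", "gene", "kind")
    one_based: bool = True
    default_kind: str = "gene"


def parse_server_table(
    text: str, dialect: TableDialect | None = None, source: str = "server"
) -> list[GenomeFeature]:
    dialect = dialect or TableDialect()
    feats: list[GenomeFeature] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            values: dict[str, str] = {}
            ti = 0
            for col in dialect.columns:
                if ti >= len(tokens):
                    break
                tok = tokens[ti]
                if col == "strand" and tok not in ("+", "-"):
                    continue  # optional column absent in this row
                values[col] = tok
                ti += 1
            start = int(values["start"])
            end = int(values["end"])
            gene = values["gene"]
            strand = values.get("strand")
            kind = values.get("kind", dialect.default_kind)
            if end < start:
                start, end = end, start
                strand = strand or "-"
            strand = strand or "+"
            lo = start - 1 if dialect.one_based else start
            parts = [(lo, end)] if dialect.one_based else [(lo, end)]
            if kind not in ("CDS", "tRNA", "rRNA", "gene", "exon", "intron"):
                kind = dialect.default_kind
            feats.append(GenomeFeature(gene, kind, strand, parts, source))
        except (KeyError, ValueError, IndexError):
            warnings.warn(f"server table line {lineno} unparseable, skipped: {line!r}")
    return feats


# ---------------------------------------------------------------------------
# annotation union
# ---------------------------------------------------------------------------


@dataclass
class AnnotationUnion:
    features: list[GenomeFeature]
    conflicts: list[tuple[str, tuple, tuple]] = field(default_factory=list)


def _coords_key(f: GenomeFeature) -> tuple:
    return (f.gene, f.kind, f.strand, tuple(f.parts))


def union_annotations(
    set_a: list[GenomeFeature], set_b: list[GenomeFeature]
) -> AnnotationUnion:
    """Union of two annotation sets: coordinate-identical features collapse
    to one entry tagged with both sources; same (gene, kind) with different
    coordinates are both retained and listed as conflicts for the validator
    to arbitrate."""
    merged: dict[tuple, GenomeFeature] = {}
    for f in list(set_a) + list(set_b):
        key = _coords_key(f)
        if key in merged:
            prev = merged[key]
            sources = sorted(set(filter(None, [prev.source, f.source])))
            merged[key] = GenomeFeature(
                prev.gene, prev.kind, prev.strand, prev.parts,
                "+".join(sources), prev.exceptions, prev.origin_spanning,
                prev.part_strands,
            )
        else:
            merged[key] = f
    features = list(merged.values())
    conflicts = []
    by_gene_kind: dict[tuple, list[GenomeFeature]] = {}
    for f in features:
        by_gene_kind.setdefault((f.gene, f.kind), []).append(f)
    for (gene, _kind), fs in by_gene_kind.items():
        if len(fs) > 1:
            for i in range(len(fs)):
                for j in range(i + 1, len(fs)):
                    conflicts.append((gene, tuple(fs[i].parts), tuple(fs[j].parts)))
    return AnnotationUnion(features, conflicts)


# ---------------------------------------------------------------------------
# CDS validation
# ---------------------------------------------------------------------------


@dataclass
class CdsValidationReport:
    gene: str
    checks: dict[str, bool]
    action: str
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())


def _checks(cds: str) -> dict[str, bool]:
    len3 = len(cds) % 3 == 0
    internal = False
    if len(cds) >= 6:
        for i in range(3, (len(cds) // 3 - 1) * 3, 3):
            if cds[i : i + 3] in STOP_CODONS:
                internal = True
                break
    return {
        "has_start": cds[:3] in START_CODONS,
        "has_stop": len3 and cds[-3:] in STOP_CODONS,
        "no_internal_stop": not internal,
        "len_multiple_of_3": len3,
    }


def _extend(feature: GenomeFeature, up: int, down: int, genome_len: int) -> GenomeFeature:
    """Extend the transcript start by ``up`` bp and the end by ``down`` bp."""
    parts = list(feature.parts)
    first_strand = feature.strand_of_part(0)
    last_strand = feature.strand_of_part(len(parts) - 1)
    s, e = parts[0]
    parts[0] = (s - up, e) if first_strand == "+" else (s, e + up)
    s, e = parts[-1]
    parts[-1] = (s, e + down) if last_strand == "+" else (s - down, e)
    for s, e in parts:
        if s < 0 or e > genome_len:
            raise ValueError("extension leaves genome bounds")
    return GenomeFeature(
        feature.gene, feature.kind, feature.strand, parts, feature.source,
        list(feature.exceptions), feature.origin_spanning,
        list(feature.part_strands) if feature.part_strands else None,
    )


def validate_cds(
    feature: GenomeFeature,
    genome: NucleotideSequence,
    rescue_window: int = 50,
) -> tuple[GenomeFeature, CdsValidationReport]:
    if feature.kind != "CDS":
        raise ValueError(f"validate_cds requires a CDS feature, got {feature.kind}")
    cds = feature.extract(genome)
    checks = _checks(cds)
    if all(checks.values()):
        return feature, CdsValidationReport(feature.gene, checks, "accepted")

    notes: list[str] = []
    up_ext = down_ext = 0
    adjusted = feature

    if not checks["has_start"]:
        for k in range(3, rescue_window + 1, 3):
            try:
                cand = _extend(feature, k, 0, len(genome))
            except ValueError:
                break
            if cand.extract(genome)[:3] in START_CODONS:
                up_ext = k
                adjusted = cand
                notes.append(f"start codon found {k} bp upstream")
                break

    if not checks["has_stop"] and checks["len_multiple_of_3"]:
        for k in range(3, rescue_window + 1, 3):
            try:
                cand = _extend(adjusted, 0, k, len(genome))
            except ValueError:
                break
            ext = cand.extract(genome)
            if ext[-3:] in STOP_CODONS:
                down_ext = k
                adjusted = cand
                notes.append(f"stop codon found {k} bp downstream")
                break

    final_checks = _checks(adjusted.extract(genome))
    if (up_ext or down_ext) and all(final_checks.values()):
        if up_ext and down_ext:
            action = f"extended_upstream({up_ext})+extended_downstream({down_ext})"
        elif up_ext:
            action = f"extended_upstream({up_ext})"
        else:
            action = f"extended_downstream({down_ext})"
        return adjusted, CdsValidationReport(feature.gene, final_checks, action, notes)

    if not checks["has_start"] and cds[:3] == "ACG":
        adjusted = GenomeFeature(
            feature.gene, feature.kind, feature.strand, feature.parts,
            feature.source,
            list(feature.exceptions) + ["RNA editing of the start codon"],
            feature.origin_spanning,
            list(feature.part_strands) if feature.part_strands else None,
        )
        notes.append("ACG initiator: RNA editing of the start codon suspected")
        return adjusted, CdsValidationReport(feature.gene, checks, "exception_added", notes)

    if not checks["no_internal_stop"] and len(feature.parts) > 1:
        notes.append("internal stop in multi-exon gene: exon boundaries need re-evaluation")
    return feature, CdsValidationReport(feature.gene, checks, "flagged", notes)


# ---------------------------------------------------------------------------
# gene-content summary
# ---------------------------------------------------------------------------


@dataclass
class GeneContentSummary:
    n_unique_genes: int
    n_cds: int
    n_cds_dup_ir: int
    n_trna: int
    n_trna_dup_ir: int
    n_rrna: int
    n_rrna_dup_ir: int
    coding_fraction: float
    gene_density: float
    gc_percent: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _part_in(iv: tuple[int, int], region: tuple[int, int], L: int) -> bool:
    s, e = region
    if s <= e:
        return s <= iv[0] and iv[1] <= e
    return iv[0] >= s or iv[1] <= e


def gene_content_summary(
    genome: AnnotatedGenome, partition: QuadripartitePartition | None = None
) -> GeneContentSummary:
    """Tabulate gene content the way plastome papers report it.

    Unique genes are counted by name (the two IR copies collapse to one); a
    gene is duplicated-in-IR when it has a copy (or, for trans-spliced genes,
    an exon) wholly inside each IR.  ``coding_fraction`` is the fraction of
    genome positions covered by any CDS/tRNA/rRNA feature, and
    ``gene_density`` counts gene copies (unique + IR duplicates) per kb.
    """
    L = len(genome.sequence)
    by_kind: dict[str, dict[str, list[GenomeFeature]]] = {"CDS": {}, "tRNA": {}, "rRNA": {}}
    for f in genome.features:
        if f.kind in by_kind:
            by_kind[f.kind].setdefault(f.gene, []).append(f)

    dup_counts: dict[str, int] = {}
    for kind, genes in by_kind.items():
        dup = 0
        if partition is not None:
            for gene, fs in genes.items():
                in_irb = any(
                    all(_part_in(p, partition.irb, L) for p in f.parts) for f in fs
                ) or any(
                    any(_part_in(p, partition.irb, L) for p in f.parts)
                    for f in fs
                    if len(f.parts) > 1
                )
                in_ira = any(
                    all(_part_in(p, partition.ira, L) for p in f.parts) for f in fs
                ) or any(
                    any(_part_in(p, partition.ira, L) for p in f.parts)
                    for f in fs
                    if len(f.parts) > 1
                )
                if in_irb and in_ira:
                    dup += 1
        dup_counts[kind] = dup

    n_cds, n_trna, n_rrna = (len(by_kind[k]) for k in ("CDS", "tRNA", "rRNA"))
    n_unique = n_cds + n_trna + n_rrna

    covered = np.zeros(L, dtype=bool)
    for f in genome.features:
        if f.kind in ("CDS", "tRNA", "rRNA"):
            for s, e in f.parts:
                covered[s:e] = True
    n_dup_total = sum(dup_counts.values())
    return GeneContentSummary(
        n_unique_genes=n_unique,
        n_cds=n_cds,
        n_cds_dup_ir=dup_counts["CDS"],
        n_trna=n_trna,
        n_trna_dup_ir=dup_counts["tRNA"],
        n_rrna=n_rrna,
        n_rrna_dup_ir=dup_counts["rRNA"],
        coding_fraction=float(covered.mean()),
        gene_density=round((n_unique + n_dup_total) / (L / 1000.0), 2),
        gc_percent=round(gc_fraction(genome.sequence.residues) * 100, 1),
    )
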