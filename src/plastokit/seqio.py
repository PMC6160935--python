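"""Sequence and feature data model plus FASTA/FASTQ/GFF3/GenBank readers and
writers, and translation under the plastid (bacterial, table 11) genetic code.

Coordinate convention
---------------------
All in-memory coordinates are 0-based half-open ``[start, end)``.  GFF3 and
GenBank use 1-based inclusive coordinates; the conversion happens exactly once,
at read and write time.  Features that wrap the origin of a circular genome are
stored as two parts with ``origin_spanning=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

IUPAC_NT = set("ACGTUNRYSWKMBDHV")
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "gene", "exon", "intron")


class ParseError(ValueError):
    """Raised when a sequence or annotation file violates its format."""


@dataclass
class NucleotideSequence:
    """A named nucleotide sequence, optionally circular."""

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - IUPAC_NT
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Extract ``[start, end)``; on circular sequences the interval may wrap."""
        n = len(self.residues)
        if 0 <= start <= end <= n:
            return self.residues[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) out of bounds for linear sequence")
        start %= n
        end %= n
        if start < end:
            return self.residues[start:end]
        return self.residues[start:] + self.residues[:end]


@dataclass
class QualityRead:
    """One mate of a paired-end read with Phred qualities."""

    id: str
    mate: str  # "R1" or "R2"
    residues: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if self.mate not in ("R1", "R2"):
            raise ValueError(f"mate must be R1 or R2, got {self.mate!r}")
        if len(self.qualities) != len(self.residues):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )
        if any(q < 0 or q > 60 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: Phred quality outside [0, 60]")
        self.qualities = list(self.qualities)

    def __len__(self) -> int:
        return len(self.residues)

    def trimmed(self, length: int) -> "QualityRead":
        return QualityRead(
            self.id, self.mate, self.residues[:length], self.qualities[:length]
        )


@dataclass
class GenomeFeature:
    """A stranded, possibly multi-part gene feature.

    ``parts`` is a list of ``[start, end)`` intervals in *transcript* order:
    ascending genomic order for plus-strand genes, descending for minus-strand
    genes, and arbitrary for trans-spliced genes (plastid *rps12*), whose
    parts may even sit on different strands (``part_strands``).
    """

    gene: str
    kind: str
    strand: str
    parts: list[tuple[int, int]]
    source: str = ""
    exceptions: list[str] = field(default_factory=list)
    origin_spanning: bool = False
    part_strands: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("feature gene name is empty")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.parts = [(int(s), int(e)) for s, e in self.parts]
        for s, e in self.parts:
            if e <= s:
                raise ValueError(f"feature {self.gene}: empty/inverted part [{s},{e})")
        ordered = sorted(self.parts)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError(f"feature {self.gene}: overlapping parts")
        if self.part_strands is not None and len(self.part_strands) != len(self.parts):
            raise ValueError(f"feature {self.gene}: part_strands length mismatch")
        if self.kind == "CDS" and self.length == 0:
            raise ValueError(f"CDS {self.gene} has zero length")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def strand_of_part(self, i: int) -> str:
        return self.part_strands[i] if self.part_strands else self.strand

    def extract(self, genome: "NucleotideSequence") -> str:
        """Spliced, strand-corrected sequence in transcript (part) order."""
        chunks = []
        for i, (s, e) in enumerate(self.parts):
            chunk = genome.slice(s, e)
            if self.strand_of_part(i) == "-":
                chunk = reverse_complement(chunk)
            chunks.append(chunk)
        return "".join(chunks)

    def shifted(self, delta: int) -> "GenomeFeature":
        return GenomeFeature(
            self.gene,
            self.kind,
            self.strand,
            [(s + delta, e + delta) for s, e in self.parts],
            self.source,
            list(self.exceptions),
            self.origin_spanning,
            list(self.part_strands) if self.part_strands else None,
        )


@dataclass
class AnnotatedGenome:
    """A genome sequence together with its gene features."""

    sequence: NucleotideSequence
    features: list[GenomeFeature]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n or f.start < 0:
                raise ValueError(
                    f"feature {f.gene} [{f.start},{f.end}) outside genome of length {n}"
                )

    def features_of_kind(self, *kinds: str) -> list[GenomeFeature]:
        return [f for f in self.features if f.kind in kinds]

    def unique_gene_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            seen.setdefault(f.gene, None)
        return list(seen)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file; raises :class:`ParseError` naming the bad line."""
    seqs: list[NucleotideSequence] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        seqs.append(NucleotideSequence(header, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line)
    flush()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(
    seqs: Iterable[NucleotideSequence], path: str | Path, wrap: int = 70
) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), wrap):
                fh.write(s.residues[i : i + wrap] + "\n")


def read_fastq(path: str | Path, mate: str = "R1") -> list[QualityRead]:
    """Read 4-line-record FASTQ with Phred+33 qualities."""
    reads: list[QualityRead] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}:{i + 1}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{i + 3}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"{path}:{i + 4}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        quals = [ord(c) - 33 for c in qual]
        reads.append(QualityRead(head[1:], mate, seq.upper(), quals))
    return reads


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.residues}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(
    features: Iterable[GenomeFeature], path: str | Path, seqid: str = "genome"
) -> None:
    """Write features as GFF3; multi-part features emit one line per part
    sharing an ``ID`` attribute, with a ``part=`` index recording transcript
    order (needed for trans-spliced genes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for idx, f in enumerate(features):
            fid = f"{f.gene}.{idx}"
            for pidx, (s, e) in enumerate(f.parts):
                attrs = [f"ID={fid}", f"Name={f.gene}", f"part={pidx}"]
                if f.exceptions:
                    attrs.append("exception=" + "|".join(f.exceptions))
                if f.origin_spanning:
                    attrs.append("origin_spanning=true")
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            f.source or ".",
                            f.kind,
                            str(s + 1),  # to 1-based inclusive
                            str(e),
                            ".",
                            f.strand_of_part(pidx),
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[GenomeFeature]:
    """Read GFF3; lines sharing an ``ID`` merge into one multi-part feature."""
    pending: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, kind, start, end, _score, strand, _phase, attr_s = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end < start")
            attrs = dict(
                kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv
            )
            if kind not in FEATURE_KINDS:
                warnings.warn(
                    f"{path}:{lineno}: unknown feature kind {kind!r}, retained as 'gene'"
                )
                kind = "gene"
            fid = attrs.get("ID", f"_line{lineno}")
            name = attrs.get("Name", attrs.get("gene", fid))
            part_idx = int(attrs.get("part", 0))
            rec = pending.get(fid)
            if rec is None:
                rec = {
                    "gene": name,
                    "kind": kind,
                    "source": source if source != "." else "",
                    "parts": [],
                    "exceptions": attrs.get("exception", ""),
                    "origin_spanning": attrs.get("origin_spanning") == "true",
                }
                pending[fid] = rec
                order.append(fid)
            rec["parts"].append((part_idx, start_i - 1, end_i, strand if strand in "+-" else "+"))
    feats = []
    for fid in order:
        rec = pending[fid]
        triples = sorted(rec["parts"])
        parts = [(s, e) for _, s, e, _ in triples]
        strands = [st for _, _, _, st in triples]
        uniform = len(set(strands)) == 1
        feats.append(
            GenomeFeature(
                rec["gene"],
                rec["kind"],
                strands[0],
                parts,
                rec["source"],
                rec["exceptions"].split("|") if rec["exceptions"] else [],
                rec["origin_spanning"],
                None if uniform else strands,
            )
        )
    return feats


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_GENBANK_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "gene": "gene",
                     "exon": "exon", "intron": "intron"}


def read_genbank_flat(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    Join/complement locations map to part lists; coordinates come out 0-based
    half-open.  Feature kinds outside the internal vocabulary are retained as
    ``gene`` with a warning.  ``source`` features are skipped.
    """
    from Bio import SeqIO

    record = SeqIO.read(str(path), "genbank")
    circular = record.annotations.get("topology", "") == "circular"
    seq = NucleotideSequence(record.id or record.name, str(record.seq), circular)
    feats: list[GenomeFeature] = []
    for bf in record.features:
        if bf.type == "source":
            continue
        kind = _GENBANK_KIND_MAP.get(bf.type)
        if kind is None:
            warnings.warn(f"{path}: unknown feature kind {bf.type!r}, retained as 'gene'")
            kind = "gene"
        quals = bf.qualifiers
        gene = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or [""])[0]
        if not gene:
            continue
        strand = "-" if (bf.location.strand or 1) < 0 else "+"
        parts = [(int(p.start), int(p.end)) for p in bf.location.parts]
        # internal convention stores parts in transcript order
        if strand == "-" and parts == sorted(parts):
            parts = list(reversed(parts))
        exceptions = list(quals.get("exception", [])) + list(quals.get("transl_except", []))
        try:
            feats.append(GenomeFeature(gene, kind, strand, parts, "genbank", exceptions))
        except ValueError:
            # e.g. duplicated part coordinates in odd records; keep going
            warnings.warn(f"{path}: skipped malformed feature {gene!r}")
    return AnnotatedGenome(seq, feats)


def write_genbank_flat(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write an :class:`AnnotatedGenome` as a GenBank flat file (LOCUS /
    FEATURES / ORIGIN subset, enough to round-trip through
    :func:`read_genbank_flat`)."""
    from Bio.Seq import Seq as _Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    record = SeqRecord(
        _Seq(genome.sequence.residues),
        id=genome.sequence.id,
        name=genome.sequence.id[:16].replace(".", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.sequence.circular else "linear",
        },
    )
    for f in genome.features:
        locs = []
        for i, (s, e) in enumerate(f.parts):
            strand = 1 if f.strand_of_part(i) == "+" else -1
            locs.append(SimpleLocation(s, e, strand=strand))
        if len(locs) == 1:
            location = locs[0]
        else:
            # GenBank lists minus-strand joins in ascending genomic order
            if all(l.strand == -1 for l in locs) and [
                (int(l.start), int(l.end)) for l in locs
            ] == sorted(((int(l.start), int(l.end)) for l in locs), reverse=True):
                locs = list(reversed(locs))
            location = CompoundLocation(locs)
        quals = {"gene": [f.gene]}
        if f.exceptions:
            quals["exception"] = list(f.exceptions)
        record.features.append(SeqFeature(location, type=f.kind, qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# Translation and simple sequence arithmetic
# ---------------------------------------------------------------------------


def translate(nt: str, start: bool = False) -> str:
    """Translate under the plastid/bacterial code (table 11).

    Stops render as ``*``; ambiguity-containing codons as ``X``.  With
    ``start=True`` the first codon, if one of the table-11 initiators
    {ATG, GTG, TTG}, translates to ``M``.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    aa = str(Seq(nt).translate(table=11))
    if start and nt[:3] in START_CODONS:
        aa = "M" + aa[1:]
    return aa


def reverse_complement(nt: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes and case-folding up."""
    return str(Seq(nt.upper()).reverse_complement())


def gc_fraction(nt: str) -> float:
    """G+C over A+C+G+T; N and other ambiguity codes are excluded from both
    numerator and denominator.  Returns 0.0 for a sequence of only ambiguities."""
    if not nt:
        return 0.0
    seq = nt.upper()
    if not any(c in "ACGT" for c in seq):
        return 0.0
    return float(_bio_gc_fraction(seq, ambiguous="remove"))
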