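"""Codon-aware gene alignment and concatenation.

Coding regions are grouped by gene across genomes, translated, aligned at the
amino-acid level, and back-translated so that every indel in the nucleotide
alignment is a multiple of three and the reading frame is preserved.  The
per-gene alignments concatenate into a supermatrix with a partition table;
columns containing any gap can be stripped before phylogenetic inference.

The built-in aligner is a center-star progressive alignment over
``Bio.Align.PairwiseAligner`` (BLOSUM62, affine gaps); an external aligner
executable (e.g. ``mafft``) can be substituted through the ``aligner``
hook of :func:`align_gene` for exact replication of third-party columns.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from plastokit.seqio import STOP_CODONS, AnnotatedGenome, translate


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class GeneAlignment:
    gene: str
    taxa: list[str]
    rows: list[str]  # codon-preserving nucleotide rows with '-' gaps

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"{self.gene}: unequal row lengths {widths}")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError(f"{self.gene}: alignment width not a codon multiple")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 0-based half-open

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class AlignmentStats:
    length: int
    avg_pairwise_identity: float
    pair_identity: dict[tuple[str, str], float] = field(default_factory=dict)
    pair_differences: dict[tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def extract_cds_groups(
    genomes: list[AnnotatedGenome],
) -> dict[str, list[tuple[str, str]]]:
    """Per gene (case-insensitive name match), the (taxon, CDS) pairs.

    Exons join in transcript (part) order with minus-strand parts
    reverse-complemented; IR-duplicated copies collapse to the first
    occurrence per taxon; CDSs whose length is not a multiple of three are
    excluded with a warning.
    """
    groups: dict[str, list[tuple[str, str]]] = {}
    canonical: dict[str, str] = {}
    for genome in genomes:
        taxon = genome.sequence.id
        seen: set[str] = set()
        for f in genome.features:
            if f.kind != "CDS":
                continue
            key = f.gene.casefold()
            if key in seen:
                continue  # IR duplicate
            cds = f.extract(genome.sequence)
            if len(cds) % 3 != 0:
                warnings.warn(
                    f"{taxon}:{f.gene}: CDS length {len(cds)} not a multiple of 3; excluded"
                )
                continue
            seen.add(key)
            canonical.setdefault(key, f.gene)
            groups.setdefault(key, []).append((taxon, cds))
    return {canonical[k]: v for k, v in groups.items()}


# ---------------------------------------------------------------------------
# amino-acid MSA (center-star progressive) and back-translation
# ---------------------------------------------------------------------------


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _kmer_similarity(a: str, b: str, k: int = 3) -> float:
    ka = Counter(a[i : i + k] for i in range(max(1, len(a) - k + 1)))
    kb = Counter(b[i : i + k] for i in range(max(1, len(b) - k + 1)))
    shared = sum((ka & kb).values())
    return shared / max(1, min(sum(ka.values()), sum(kb.values())))


def _center_star_msa(seqs: list[str]) -> list[str]:
    """Center-star multiple alignment of amino-acid sequences."""
    n = len(seqs)
    if n == 1:
        return list(seqs)
    aligner = _protein_aligner()
    # center = sequence with greatest total k-mer similarity to the others
    totals = [
        sum(_kmer_similarity(seqs[i], seqs[j]) for j in range(n) if j != i)
        for i in range(n)
    ]
    center = int(np.argmax(totals))
    others = sorted(
        (j for j in range(n) if j != center),
        key=lambda j: -_kmer_similarity(seqs[center], seqs[j]),
    )
    msa = [seqs[center]]
    order = [center]
    for j in others:
        aln = aligner.align(msa[0].replace("-", ""), seqs[j])[0]
        center_gapped, new_gapped = str(aln[0]), str(aln[1])
        # re-project the pairwise center row onto the current msa center row
        msa = _merge_rows(msa, center_gapped, new_gapped)
        order.append(j)
    # restore input order
    out = [""] * n
    for row, idx in zip(msa, order):
        out[idx] = row
    return out


def _merge_rows(msa_rows: list[str], center_gapped: str, new_gapped: str) -> list[str]:
    """Merge pairwise (ungapped-center vs new) into the MSA (gapped center)."""
    old_center = msa_rows[0]
    out = ["" for _ in range(len(msa_rows) + 1)]
    i = j = 0
    n_old, n_new = len(old_center), len(center_gapped)
    while i < n_old or j < n_new:
        a = old_center[i] if i < n_old else "-"
        b = center_gapped[j] if j < n_new else "-"
        if i < n_old and a == "-":
            # column where center already gapped (earlier insertion)
            for r, row in enumerate(msa_rows):
                out[r] += row[i]
            out[-1] += "-"
            i += 1
        elif j < n_new and b == "-":
            # new sequence inserts relative to the center
            out[0] += "-"
            for r in range(1, len(msa_rows)):
                out[r] += "-"
            out[-1] += new_gapped[j]
            j += 1
        else:
            for r, row in enumerate(msa_rows):
                out[r] += row[i]
            out[-1] += new_gapped[j]
            i += 1
            j += 1
    return out


def _mafft_msa(seqs: list[str], executable: str = "mafft") -> list[str]:
    """External-aligner hook: align amino-acid sequences with mafft."""
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        with open(inp, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        res = subprocess.run(
            [executable, "--auto", "--amino", "--quiet", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
        rows: dict[str, str] = {}
        name = None
        for line in res.stdout.splitlines():
            if line.startswith(">"):
                name = line[1:].strip()
                rows[name] = ""
            elif name:
                rows[name] += line.strip()
        return [rows[f"s{i}"].upper() for i in range(len(seqs))]


def align_gene(
    gene: str,
    group: list[tuple[str, str]],
    aligner: str = "builtin",
) -> GeneAlignment:
    """Protein-guided codon alignment of one gene's CDSs.

    Terminal stop codons are trimmed before alignment and restored after (as
    a final codon column block); internal stops are an error.  ``aligner``
    is ``"builtin"`` or the name/path of an external amino-acid aligner
    executable (mafft-compatible interface).
    """
    taxa = [t for t, _ in group]
    cdss = []
    stops = []
    for taxon, cds in group:
        cds = cds.upper()
        if cds[-3:] in STOP_CODONS:
            stops.append(cds[-3:])
            cds = cds[:-3]
        else:
            stops.append(None)
        aa = translate(cds, start=True)
        if "*" in aa:
            raise ValueError(f"internal stop codon in {taxon}:{gene}")
        cdss.append(cds)
    aas = [translate(c, start=True) for c in cdss]
    if aligner == "builtin":
        aligned = _center_star_msa(aas)
    else:
        aligned = _mafft_msa(aas, aligner)
    rows = []
    for aa_row, cds in zip(aligned, cdss):
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        out = []
        ci = 0
        for ch in aa_row:
            if ch == "-":
                out.append("---")
            else:
                out.append(codons[ci])
                ci += 1
        if ci != len(codons):
            raise AssertionError(f"{gene}: back-translation consumed {ci}/{len(codons)} codons")
        rows.append("".join(out))
    if any(s is not None for s in stops):
        rows = [r + (s if s is not None else "---") for r, s in zip(rows, stops)]
    return GeneAlignment(gene, taxa, rows)


# ---------------------------------------------------------------------------
# concatenation, gap removal, statistics
# ---------------------------------------------------------------------------


def concatenate(
    gene_alignments: list[GeneAlignment], taxa: list[str] | None = None
) -> Supermatrix:
    """Concatenate per-gene alignments in lexicographic gene order; taxa
    missing a gene receive an all-gap block of that gene's width."""
    if taxa is None:
        seen: dict[str, None] = {}
        for ga in gene_alignments:
            for t in ga.taxa:
                seen.setdefault(t, None)
        taxa = sorted(seen)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for ga in sorted(gene_alignments, key=lambda g: g.gene):
        width = ga.width
        row_of = dict(zip(ga.taxa, ga.rows))
        for t in taxa:
            chunks[t].append(row_of.get(t, "-" * width))
        parts.append((ga.gene, pos, pos + width))
        pos += width
    return Supermatrix(list(taxa), ["".join(chunks[t]) for t in taxa], parts)


def remove_gap_columns(
    matrix: Supermatrix, missing: str = "-?"
) -> tuple[Supermatrix, AlignmentStats, AlignmentStats]:
    """Drop every column holding a gap/missing symbol in any row; partition
    ranges are remapped.  Returns the stripped matrix plus alignment
    statistics before and after."""
    before = alignment_stats(matrix)
    arr = np.array([list(r) for r in matrix.rows])
    keep = ~np.isin(arr, list(missing)).any(axis=0)
    stripped = ["".join(row) for row in arr[:, keep]]
    kept_cum = np.concatenate([[0], np.cumsum(keep)])
    partitions = []
    for gene, s, e in matrix.partitions:
        ns, ne = int(kept_cum[s]), int(kept_cum[e])
        partitions.append((gene, ns, ne))
    out = Supermatrix(matrix.taxa, stripped, partitions)
    return out, before, alignment_stats(out)


def alignment_stats(matrix: Supermatrix, missing: str = "-?") -> AlignmentStats:
    """Pairwise identity over columns where at least one of the pair is
    non-gap (gap-vs-residue counts as non-identical); differences count
    columns where both are non-gap and differ."""
    if len(matrix.rows) < 2:
        raise ValueError("alignment statistics require at least 2 rows")
    arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in matrix.rows])
    gap = np.isin(arr, [m.encode() for m in missing])
    ids: dict[tuple[str, str], float] = {}
    diffs: dict[tuple[str, str], int] = {}
    n = len(matrix.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            either = ~(gap[i] & gap[j])
            both = ~(gap[i] | gap[j])
            same = both & (arr[i] == arr[j])
            denom = int(either.sum())
            key = (matrix.taxa[i], matrix.taxa[j])
            ids[key] = float(same.sum() / denom) if denom else 1.0
            diffs[key] = int((both & (arr[i] != arr[j])).sum())
    avg = float(np.mean(list(ids.values())))
    return AlignmentStats(matrix.width, avg, ids, diffs)


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------


def write_supermatrix_nexus(matrix: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.width};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        pad = max(len(t) for t in matrix.taxa) + 2
        for t, row in zip(matrix.taxa, matrix.rows):
            fh.write(f"    {t:<{pad}}{row}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for gene, s, e in matrix.partitions:
            fh.write(f"  CHARSET {gene} = {s + 1}-{e};\n")
        fh.write("END;\n")


def write_supermatrix_fasta(matrix: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for t, row in zip(matrix.taxa, matrix.rows):
            fh.write(f">{t}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


def read_alignment_fasta(path) -> Supermatrix:
    taxa: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if taxa:
                    rows.append("".join(current))
                taxa.append(line[1:].split()[0])
                current = []
            else:
                current.append(line.upper())
    if taxa:
        rows.append("".join(current))
    width = len(rows[0]) if rows else 0
    return Supermatrix(taxa, rows, [("all", 0, width)])
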