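"""Ground-truth generator: synthetic quadripartite plastomes with gene
annotations, families of descendant genomes evolved under GTR+I+G on a known
tree, and paired short reads with Phred qualities, sequencing errors, adapter
read-through and orphaned mates.

Every other module is testable against these generators without downloading
anything: the plastome builder guarantees its own IR equality, gene validity
and trans-spliced *rps12* layout; the read simulator writes a truth table
(fragment origin, adapter and orphan flags) alongside the reads.

Default dimensions mirror the magnitudes plastome papers report for water
lilies and their relatives: LSC ~89 kb, SSC ~19 kb, IR ~25 kb, 116 unique
genes (82 protein-coding / 30 tRNA / 4 rRNA, of which 9/7/4 sit inside each
IR), GC ~0.38, MiSeq-like 2x300 bp pairs from ~550 bp fragments.  A 10x
scaled-down spec (:meth:`PlastomeSpec.small`) keeps routine tests fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from plastokit.assemblyfinish import QuadripartitePartition
from plastokit.phylo import GTRIGModel, TreeNode
from plastokit.seqio import (
    STOP_CODONS,
    AnnotatedGenome,
    GenomeFeature,
    NucleotideSequence,
    QualityRead,
    reverse_complement,
)

_CODE = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class PlastomeSpec:
    lsc_len: int = 89_000
    ssc_len: int = 19_000
    ir_len: int = 25_400
    n_cds: int = 82
    n_trna: int = 30
    n_rrna: int = 4
    n_cds_in_ir: int = 9
    n_trna_in_ir: int = 7
    n_rrna_in_ir: int = 4
    gc_target: float = 0.38
    coding_target: float = 0.69
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")
        if self.n_cds_in_ir >= self.n_cds:
            raise ValueError("n_cds_in_ir must leave CDSs outside the IR")

    @classmethod
    def small(cls, seed: int = 0) -> "PlastomeSpec":
        """10x scaled-down spec for fast tests."""
        return cls(
            lsc_len=8_900, ssc_len=1_900, ir_len=2_540,
            n_cds=14, n_trna=5, n_rrna=2,
            n_cds_in_ir=2, n_trna_in_ir=1, n_rrna_in_ir=1,
            seed=seed,
        )


@dataclass
class ReadSimSpec:
    coverage: float = 200.0
    read_len: int = 300
    insert_mean: float = 550.0
    insert_sd: float = 60.0
    error_rate: float = 0.001
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"  # TruSeq read-1 adapter
    adapter_rate: float = 0.05
    orphan_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.adapter_rate, self.orphan_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.coverage <= 0 or not 0 <= self.error_rate < 1:
            raise ValueError("invalid coverage or error rate")


# real plastid gene names to draw from, padded with ycf/orf placeholders
_CDS_NAMES = (
    "psbA matK rbcL atpA atpB atpE atpF atpH atpI rpoA rpoB rpoC1 rpoC2 "
    "petA petB petD psaA psaB psaC psaI psaJ psbB psbC psbD psbE psbF psbH "
    "psbI psbJ psbK psbL psbM psbN psbT psbZ ndhA ndhB ndhC ndhD ndhE ndhF "
    "ndhG ndhH ndhI ndhJ ndhK rpl2 rpl14 rpl16 rpl20 rpl22 rpl23 rpl32 "
    "rpl33 rpl36 rps2 rps3 rps4 rps7 rps8 rps11 rps14 rps15 rps16 rps18 "
    "rps19 accD ccsA cemA clpP infA matR ycf1 ycf2 ycf3 ycf4 ycf15"
).split()
_TRNA_NAMES = (
    "trnA-UGC trnC-GCA trnD-GUC trnE-UUC trnF-GAA trnG-GCC trnH-GUG "
    "trnI-CAU trnK-UUU trnL-CAA trnL-UAA trnM-CAU trnN-GUU trnP-UGG "
    "trnQ-UUG trnR-ACG trnS-GCU trnS-UGA trnT-GGU trnV-GAC trnW-CCA "
    "trnY-GUA trnfM-CAU trnG-UCC trnI-GAU trnL-UAG trnR-UCU trnS-GGA "
    "trnT-UGU trnV-UAC"
).split()
_RRNA_NAMES = ["rrn16", "rrn23", "rrn4.5", "rrn5"]


def _gene_names(prefix_pool: list[str], n: int, fallback: str) -> list[str]:
    names = list(prefix_pool[:n])
    for i in range(len(names), n):
        names.append(f"{fallback}{i + 1}")
    return names


# ---------------------------------------------------------------------------
# plastome construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return b"".join(rng.choice(_CODE, size=n, p=p)).decode()


def _codon_pool(gc: float) -> tuple[list[str], np.ndarray]:
    """Non-stop codons with weights whose expected GC equals ``gc``.

    Excluding the (AT-rich) stop codons shifts the naive codon distribution
    toward G+C, so the per-base GC used for weighting is corrected once."""
    bases = "ACGT"
    codons = [
        a + b + c
        for a in bases for b in bases for c in bases
        if a + b + c not in STOP_CODONS
    ]

    def weights_for(g: float) -> np.ndarray:
        pb = {"A": (1 - g) / 2, "C": g / 2, "G": g / 2, "T": (1 - g) / 2}
        w = np.array([pb[x[0]] * pb[x[1]] * pb[x[2]] for x in codons])
        return w / w.sum()

    w = weights_for(gc)
    gc_per_codon = np.array([sum(c in "GC" for c in x) / 3 for x in codons])
    realized = float(w @ gc_per_codon)
    w = weights_for(max(0.05, min(0.95, gc - (realized - gc))))
    return codons, w


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random non-stop codons + a stop; codon weights follow gc."""
    codons, weights = _codon_pool(gc)
    body = rng.choice(codons, size=n_codons - 2, p=weights)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(body) + stop


@dataclass
class _Slot:
    gene: str
    kind: str
    strand: str
    seq: str  # transcript-orientation sequence
    tag: str = ""  # "" ordinary; "rps12_exon1|2|3" for the trans-spliced parts


def _layout_region(
    rng: np.random.Generator, slots: list[_Slot], region_len: int, gc: float
) -> tuple[str, list[tuple[_Slot, int, int]]]:
    """Place slots left-to-right with random intergenic gaps; returns the
    region sequence and each slot's [start, end) within the region."""
    total = sum(len(s.seq) for s in slots)
    n_gaps = len(slots) + 1
    spare = region_len - total - 10 * n_gaps
    if spare < 0:
        raise ValueError(
            f"infeasible packing: {total} bp of genes in a {region_len} bp region"
        )
    cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1))
    gap_lens = np.diff(np.concatenate([[0], cuts, [spare]])) + 10
    pieces: list[str] = []
    placed: list[tuple[_Slot, int, int]] = []
    pos = 0
    for slot, gap in zip(slots, gap_lens[:-1]):
        pieces.append(_random_seq(rng, int(gap), gc))
        pos += int(gap)
        genomic = slot.seq if slot.strand == "+" else reverse_complement(slot.seq)
        pieces.append(genomic)
        placed.append((slot, pos, pos + len(genomic)))
        pos += len(genomic)
    pieces.append(_random_seq(rng, int(gap_lens[-1]), gc))
    return "".join(pieces), placed


def make_plastome(spec: PlastomeSpec) -> tuple[AnnotatedGenome, QuadripartitePartition]:
    """Build a synthetic circular quadripartite plastome with its truth
    partition.  IRa is exactly the reverse complement of IRb; every CDS starts
    ATG, ends with a stop, has no internal stops and a length divisible by 3;
    one trans-spliced 3-exon gene (*rps12*) has exon 1 in the LSC and exons
    2-3 inside the IR (hence duplicated)."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_target

    cds_names = _gene_names(_CDS_NAMES, spec.n_cds - 1, "orf")  # rps12 extra
    trna_names = _gene_names(_TRNA_NAMES, spec.n_trna, "trnX")
    rrna_names = _gene_names(_RRNA_NAMES, spec.n_rrna, "rrnX")

    # capacity-aware length budgets per region (aim at the coding target)
    def cds_len(budget: int) -> int:
        n_codons = max(60, int(budget // 3))
        return n_codons

    regions: dict[str, list[_Slot]] = {"LSC": [], "SSC": [], "IR": []}

    # rps12: total length multiple of 3, exons 114 + 232 + 26 bp
    rps12_cds = _random_cds(rng, 124, gc)  # 372 bp
    regions["LSC"].append(_Slot("rps12", "CDS", "+", rps12_cds[:114], "rps12_exon1"))
    regions["IR"].append(_Slot("rps12", "CDS", "+", rps12_cds[114:346], "rps12_exon2"))
    regions["IR"].append(_Slot("rps12", "CDS", "+", rps12_cds[346:], "rps12_exon3"))

    # the IR-duplicated CDS count includes the trans-spliced rps12
    n_whole_ir_cds = max(0, spec.n_cds_in_ir - 1)
    ir_cds = cds_names[:n_whole_ir_cds]
    sc_cds = cds_names[n_whole_ir_cds:]
    ir_trna = trna_names[: spec.n_trna_in_ir]
    sc_trna = trna_names[spec.n_trna_in_ir :]
    ir_rrna = rrna_names[: spec.n_rrna_in_ir]
    sc_rrna = rrna_names[spec.n_rrna_in_ir :]

    # split single-copy genes between LSC and SSC proportionally to length
    n_sc = len(sc_cds)
    n_ssc_cds = max(1, round(n_sc * spec.ssc_len / (spec.lsc_len + spec.ssc_len)))
    ssc_cds, lsc_cds = sc_cds[:n_ssc_cds], sc_cds[n_ssc_cds:]

    def fill(region: str, cds: list[str], trna: list[str], rrna: list[str], region_len: int):
        slots = regions[region]
        trna_len = 72 if region_len > 5000 else 60
        rrna_len = min(1500, max(120, region_len // 12))
        fixed = sum(len(s.seq) for s in slots)
        fixed += trna_len * len(trna) + rrna_len * len(rrna)
        budget_cds = spec.coding_target * region_len - fixed
        per_cds = budget_cds / max(1, len(cds))
        draws = [
            max(25, int(rng.uniform(0.6, 1.4) * cds_len(int(per_cds))))
            for _ in cds
        ]
        # rescale so the region's coding load matches the target exactly
        # (and stays packable with its intergenic spacers)
        want = max(0, budget_cds) / 3
        have = sum(draws)
        limit = (0.85 * region_len - fixed - 10 * (len(slots) + len(cds) + len(trna) + len(rrna) + 1)) / 3
        scale = min(want, max(1, limit)) / have if have else 1.0
        draws = [max(25, int(round(d * scale))) for d in draws]
        for name, n_codons in zip(cds, draws):
            slots.append(_Slot(name, "CDS", str(rng.choice(["+", "-"])), _random_cds(rng, n_codons, gc)))
        for name in trna:
            slots.append(_Slot(name, "tRNA", str(rng.choice(["+", "-"])), _random_seq(rng, trna_len, gc)))
        for name in rrna:
            slots.append(_Slot(name, "rRNA", str(rng.choice(["+", "-"])), _random_seq(rng, rrna_len, gc)))
        rng.shuffle(slots)

    fill("LSC", lsc_cds, sc_trna, sc_rrna, spec.lsc_len)
    fill("SSC", ssc_cds, [], [], spec.ssc_len)
    fill("IR", ir_cds, ir_trna, ir_rrna, spec.ir_len)

    # rps12 exon order must survive the shuffle: exon2 before exon3 in the IR
    ir_slots = regions["IR"]
    e2 = next(i for i, s in enumerate(ir_slots) if s.tag == "rps12_exon2")
    e3 = next(i for i, s in enumerate(ir_slots) if s.tag == "rps12_exon3")
    if e3 < e2:
        ir_slots[e2], ir_slots[e3] = ir_slots[e3], ir_slots[e2]

    lsc_seq, lsc_placed = _layout_region(rng, regions["LSC"], spec.lsc_len, gc)
    ssc_seq, ssc_placed = _layout_region(rng, regions["SSC"], spec.ssc_len, gc)
    irb_seq, irb_placed = _layout_region(rng, regions["IR"], spec.ir_len, gc)

    # guard the IR junctions: the first/last bases of each single-copy region
    # must not pair, so the constructed IR is exactly the maximal repeat
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def guard(region: str) -> str:
        if region[0] == comp[region[-1]]:
            options = [b for b in "ACGT" if b != comp[region[-1]]]
            region = str(rng.choice(options)) + region[1:]
        return region

    lsc_seq = guard(lsc_seq)
    ssc_seq = guard(ssc_seq)

    ira_seq = reverse_complement(irb_seq)
    genome_seq = lsc_seq + irb_seq + ssc_seq + ira_seq
    L = len(genome_seq)
    lsc0, irb0 = 0, spec.lsc_len
    ssc0 = irb0 + spec.ir_len
    ira0 = ssc0 + spec.ssc_len

    features: list[GenomeFeature] = []
    rps12_parts: dict[str, tuple[int, int, str]] = {}

    def add(slot: _Slot, s: int, e: int, offset: int) -> None:
        if slot.tag:
            rps12_parts[slot.tag] = (s + offset, e + offset, slot.strand)
            return
        features.append(GenomeFeature(slot.gene, slot.kind, slot.strand, [(s + offset, e + offset)], "synth"))

    for slot, s, e in lsc_placed:
        add(slot, s, e, lsc0)
    for slot, s, e in irb_placed:
        add(slot, s, e, irb0)
    for slot, s, e in ssc_placed:
        add(slot, s, e, ssc0)

    # mirror IRb features into IRa (strand flipped, coordinates reflected)
    def mirror(s: int, e: int) -> tuple[int, int]:
        rel_s, rel_e = s - irb0, e - irb0
        return ira0 + spec.ir_len - rel_e, ira0 + spec.ir_len - rel_s

    for slot, s, e in irb_placed:
        if slot.tag:
            continue
        ms, me = mirror(s + irb0, e + irb0)
        flipped = "-" if slot.strand == "+" else "+"
        features.append(GenomeFeature(slot.gene, slot.kind, flipped, [(ms, me)], "synth"))

    # trans-spliced rps12: IRb copy on '+' parts, IRa copy with '-' IR parts
    e1 = rps12_parts["rps12_exon1"][:2]
    e2b = rps12_parts["rps12_exon2"][:2]
    e3b = rps12_parts["rps12_exon3"][:2]
    features.append(
        GenomeFeature("rps12", "CDS", "+", [e1, e2b, e3b], "synth")
    )
    e2a, e3a = mirror(*e2b), mirror(*e3b)
    features.append(
        GenomeFeature(
            "rps12", "CDS", "+", [e1, e2a, e3a], "synth",
            part_strands=["+", "-", "-"],
        )
    )

    genome = AnnotatedGenome(
        NucleotideSequence("synthetic_plastome", genome_seq, circular=True), features
    )
    partition = QuadripartitePartition(
        lsc=(lsc0, irb0),
        irb=(irb0, ssc0),
        ssc=(ssc0, ira0),
        ira=(ira0, L),
        genome_length=L,
    )
    return genome, partition


# ---------------------------------------------------------------------------
# sequence evolution on a tree
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("ancestor sequence must be unambiguous ACGT")
    return arr


def _decode(arr: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in arr)


def _cds_position_map(feature: GenomeFeature) -> list[tuple[int, int]]:
    """(genomic position, ancestor-strand sign) for each transcript position."""
    out = []
    for i, (s, e) in enumerate(feature.parts):
        if feature.strand_of_part(i) == "+":
            out.extend((p, +1) for p in range(s, e))
        else:
            out.extend((p, -1) for p in range(e - 1, s - 1, -1))
    return out


def evolve_genomes(
    ancestor: AnnotatedGenome,
    tree: TreeNode | str,
    model: GTRIGModel | None = None,
    frame_safe: bool = True,
    seed: int = 0,
    partition: QuadripartitePartition | None = None,
) -> tuple[dict[str, AnnotatedGenome], pd.DataFrame]:
    """Evolve the ancestor genome site-wise down ``tree`` under GTR+I+G.

    No indels are introduced, so annotations carry over with unchanged
    coordinates.  With ``frame_safe`` substitutions that would create an
    internal stop codon in any annotated CDS are rolled back.  When a
    ``partition`` is given, the IRa region of each descendant is overwritten
    with the reverse complement of its IRb (concerted IR evolution), keeping
    the quadripartite invariants intact.  Returns the leaf genomes keyed by
    taxon and a table of realized pairwise differences (whole genome and
    coding positions only).
    """
    from plastokit.phylo import _eigendecompose, _transition_matrices

    if isinstance(tree, str):
        from plastokit.phylo import parse_newick

        tree = parse_newick(tree)
    model = model or GTRIGModel()
    rng = np.random.default_rng(seed)
    root_seq = _encode(ancestor.sequence.residues)
    n = len(root_seq)

    rates = model.category_rates()
    n_cat = len(rates)
    site_class = rng.integers(0, n_cat, size=n)  # gamma category per site
    invariant = rng.random(n) < model.p_inv
    w, right, left = _eigendecompose(model)

    cds_maps = [
        _cds_position_map(f) for f in ancestor.features if f.kind == "CDS"
    ]

    leaves: dict[str, np.ndarray] = {}

    def evolve_branch(parent_seq: np.ndarray, t: float) -> np.ndarray:
        child = parent_seq.copy()
        if t > 0:
            P = _transition_matrices(w, right, left, rates * t)
            P = np.clip(P, 0, None)
            u = rng.random(n)
            for c in range(n_cat):
                sel = (site_class == c) & ~invariant
                if not sel.any():
                    continue
                cum = np.cumsum(P[c], axis=1)
                cum /= cum[:, -1:]
                draw = (u[sel, None] > cum[parent_seq[sel]]).sum(axis=1)
                child[sel] = np.minimum(draw, 3)
        if frame_safe:
            for pmap in cds_maps:
                # revert any codon that acquired an internal stop
                # (complement of state code x is 3 - x)
                for ci in range(1, len(pmap) // 3 - 1):
                    trip = pmap[3 * ci : 3 * ci + 3]
                    codon = "".join(
                        "ACGT"[child[p] if sgn > 0 else 3 - child[p]]
                        for p, sgn in trip
                    )
                    if codon in STOP_CODONS:
                        for p, _sgn in trip:
                            child[p] = parent_seq[p]
        return child

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for childnode in node.children:
            cseq = evolve_branch(seq, childnode.length)
            if childnode.is_leaf:
                leaves[childnode.name] = cseq
            else:
                walk(childnode, cseq)

    walk(tree, root_seq)

    genomes: dict[str, AnnotatedGenome] = {}
    for taxon, seq in leaves.items():
        if partition is not None:
            s_irb, e_irb = partition.irb
            s_ira, e_ira = partition.ira
            decoded = _decode(seq)
            irb = decoded[s_irb:e_irb]
            decoded = decoded[:s_ira] + reverse_complement(irb) + decoded[e_ira:]
            seq = _encode(decoded)
            leaves[taxon] = seq
        genomes[taxon] = AnnotatedGenome(
            NucleotideSequence(taxon, _decode(seq), circular=True),
            [f.shifted(0) for f in ancestor.features],
        )

    coding_mask = np.zeros(n, dtype=bool)
    seen_genes: set[str] = set()
    for f in ancestor.features:
        if f.kind == "CDS" and f.gene.casefold() not in seen_genes:
            seen_genes.add(f.gene.casefold())
            for s, e in f.parts:
                coding_mask[s:e] = True

    taxa = sorted(leaves)
    rows = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            a, b = leaves[taxa[i]], leaves[taxa[j]]
            diff = a != b
            rows.append(
                {
                    "taxon_a": taxa[i],
                    "taxon_b": taxa[j],
                    "n_diff_genome": int(diff.sum()),
                    "n_diff_coding": int((diff & coding_mask).sum()),
                }
            )
    return genomes, pd.DataFrame(rows)


def mutate_cds_family(
    cds: str,
    n_seqs: int,
    sub_rate: float = 0.01,
    indel_rate: float = 0.02,
    max_indel_codons: int = 3,
    seed: int = 0,
) -> list[str]:
    """Derive a family of valid CDSs from one ancestor by codon-level
    substitutions and codon-multiple indels (for alignment testing).

    Substituted codons are redrawn from non-stop codons; insertions add
    random non-stop codons; deletions remove whole codons (never the first
    or last)."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    non_stop = [
        a + b + c for a in bases for b in bases for c in bases
        if a + b + c not in STOP_CODONS
    ]
    out = []
    for _ in range(n_seqs):
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        body = codons[1:-1]
        # substitutions
        for i in range(len(body)):
            if rng.random() < sub_rate:
                body[i] = non_stop[rng.integers(len(non_stop))]
        # indels
        i = 1
        while i < len(body):
            if rng.random() < indel_rate:
                k = int(rng.integers(1, max_indel_codons + 1))
                if rng.random() < 0.5 and len(body) > k + 2:
                    del body[i : i + k]
                else:
                    ins = [non_stop[rng.integers(len(non_stop))] for _ in range(k)]
                    body[i:i] = ins
                    i += k
            i += 1
        out.append(codons[0] + "".join(body) + codons[-1])
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    genome: NucleotideSequence | AnnotatedGenome,
    sim: ReadSimSpec,
) -> tuple[list[QualityRead], list[QualityRead], pd.DataFrame]:
    """Simulate paired-end reads from a circular genome.

    Fragments are drawn uniformly over the circle at the depth implied by
    ``coverage``; R1 reads the fragment 5' end, R2 the reverse complement of
    the 3' end.  Per-base errors occur at ``error_rate`` with Phred scores
    consistent with the error model (q = -10 log10 p, jittered, floored at
    2); adapter read-through is appended when the insert is shorter than the
    read and, additionally, on an ``adapter_rate`` fraction of reads;
    an ``orphan_rate`` fraction of pairs loses one mate.  Returns R1 reads,
    R2 reads (orphaned mates omitted) and the truth table.
    """
    if isinstance(genome, AnnotatedGenome):
        genome = genome.sequence
    rng = np.random.default_rng(sim.seed)
    L = len(genome)
    n_pairs = int(round(sim.coverage * L / (2 * sim.read_len)))
    doubled = genome.residues + genome.residues  # circular fragments

    r1_out: list[QualityRead] = []
    r2_out: list[QualityRead] = []
    truth_rows = []

    def apply_errors(seq: str) -> tuple[str, list[int], int]:
        n = len(seq)
        p_err = np.clip(
            sim.error_rate * np.exp(rng.normal(0, 0.3, size=n)), 1e-5, 0.75
        ) if sim.error_rate > 0 else np.full(n, 1e-4)
        quals = np.clip(np.rint(-10 * np.log10(p_err)), 2, 41).astype(int)
        if sim.error_rate > 0:
            hits = np.nonzero(rng.random(n) < p_err)[0]
        else:
            hits = np.array([], dtype=int)
        if len(hits):
            chars = list(seq)
            for h in hits:
                alternatives = [c for c in "ACGT" if c != chars[h]]
                chars[h] = alternatives[rng.integers(3)]
            seq = "".join(chars)
        return seq, quals.tolist(), len(hits)

    for i in range(n_pairs):
        rid = f"frag{i:07d}"
        start = int(rng.integers(0, L))
        insert = max(50, int(rng.normal(sim.insert_mean, sim.insert_sd)))
        insert = min(insert, L)
        frag = doubled[start : start + insert]
        readthrough = max(0, sim.read_len - insert)
        extra_adapter = 0
        if readthrough == 0 and rng.random() < sim.adapter_rate:
            extra_adapter = int(rng.integers(15, min(41, len(sim.adapter) + 1)))
        core1 = frag[: sim.read_len]
        core2 = reverse_complement(frag[-sim.read_len :] if insert >= sim.read_len else frag)
        if readthrough > 0:
            s1 = (frag + sim.adapter)[: sim.read_len]
            s2 = (reverse_complement(frag) + sim.adapter)[: sim.read_len]
            a_len = min(readthrough, len(sim.adapter))
        elif extra_adapter > 0:
            s1 = core1[: sim.read_len - extra_adapter] + sim.adapter[:extra_adapter]
            s2 = core2[: sim.read_len - extra_adapter] + sim.adapter[:extra_adapter]
            a_len = extra_adapter
        else:
            s1, s2 = core1, core2
            a_len = 0
        s1, q1, e1 = apply_errors(s1)
        s2, q2, e2 = apply_errors(s2)
        orphan = ""
        if rng.random() < sim.orphan_rate:
            orphan = "R1" if rng.random() < 0.5 else "R2"
        if orphan != "R1":
            r1_out.append(QualityRead(rid, "R1", s1, q1))
        if orphan != "R2":
            r2_out.append(QualityRead(rid, "R2", s2, q2))
        truth_rows.append(
            {
                "read_id": rid,
                "start": start,
                "insert_len": insert,
                "adapter_len": a_len,
                "orphan": orphan,
                "n_errors_r1": e1,
                "n_errors_r2": e2,
            }
        )
    return r1_out, r2_out, pd.DataFrame(truth_rows)
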