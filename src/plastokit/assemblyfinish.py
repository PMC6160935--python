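"""Assembly finishing for plastid genomes.

Automates the finishing steps that turn reference-ordered contigs into a
complete, canonical quadripartite plastome:

* position and orient contigs against a reference genome (k-mer seeding),
* stitch adjacent contigs whose ends overlap (>= 50 nt, < 10% dissimilarity),
* place reads on a draft by exact 31-mer seeding + ungapped extension,
  keeping all equally-good placements (reads from the two inverted-repeat
  copies then pile up at twice the single-copy depth on a one-copy draft),
* detect the inverted repeat (IR) either from that coverage doubling or by
  comparing the sequence against its own reverse complement,
* complete the assembly by appending the reverse-complemented IR,
* resolve IUPAC ambiguities by majority vote over covering reads,
* partition the finished genome into LSC / IRb / SSC / IRa, and
* compute assembly and contig quality statistics (mapping rate, depth
  thresholds, N50/L50).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from plastokit.seqio import NucleotideSequence, QualityRead, reverse_complement

# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    id: str
    residues: str
    orientation: str = "as-is"  # or "reverse-complemented"
    ref_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"contig {self.id!r} is empty")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Placement:
    """An ungapped placement of one read mate on a target sequence."""

    read_id: str
    mate: str
    start: int
    length: int
    strand: str  # '+' read as-is, '-' read reverse-complemented
    mismatches: int
    oriented: str  # read residues in target orientation


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals tiling a circular plastome.

    Intervals are 0-based half-open; an interval with start > end wraps the
    origin.  ``lsc`` is by definition the longer single-copy region.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    def _ilen(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return e - s if s <= e else self.genome_length - s + e

    @property
    def lsc_length(self) -> int:
        return self._ilen(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._ilen(self.ssc)

    @property
    def ir_length(self) -> int:
        return self._ilen(self.irb)

    def __post_init__(self) -> None:
        if self._ilen(self.ira) != self._ilen(self.irb):
            raise ValueError("IRa and IRb lengths differ")
        total = sum(self._ilen(iv) for iv in (self.lsc, self.irb, self.ssc, self.ira))
        if total != self.genome_length:
            raise ValueError(
                f"partition does not tile the genome: {total} != {self.genome_length}"
            )
        if self.lsc_length < self.ssc_length:
            raise ValueError("LSC must be the longer single-copy region")

    def contains(self, iv: tuple[int, int], region: tuple[int, int]) -> bool:
        """Is ``iv`` (non-wrapping) wholly within ``region``?"""
        s, e = region
        if s <= e:
            return s <= iv[0] and iv[1] <= e
        return iv[0] >= s or iv[1] <= e


@dataclass
class StitchReport:
    merges: list[tuple[str, str, int, int]] = field(default_factory=list)  # idA,idB,ovl,mm
    gaps: list[tuple[str, str]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


@dataclass
class AssemblyStats:
    n_mapped: int
    p_mapped: float
    mean_read_len: float
    mean_depth: float
    p_ge_20x: float
    p_ge_50x: float
    p_ge_100x: float

    def __post_init__(self) -> None:
        if not (self.p_ge_20x >= self.p_ge_50x >= self.p_ge_100x):
            raise ValueError("depth-threshold fractions must be monotone")


@dataclass
class ContigStats:
    n_contigs: int
    largest: int
    total: int
    n50: int
    l50: int


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


# ---------------------------------------------------------------------------
# contig positioning and stitching
# ---------------------------------------------------------------------------


def position_contigs(
    contigs: list[Contig], reference: NucleotideSequence, k: int = 31, stride: int = 25
) -> tuple[list[Contig], list[Contig]]:
    """Assign each contig an offset and orientation on ``reference``.

    Seeds k-mers of the contig (both orientations) against the reference and
    takes the modal seed offset.  A contig from an inverted repeat matches
    the reference equally well at both IR copies (in opposite orientations);
    such near-tied candidates are resolved in a second pass by preferring
    the placement most contiguous with the unambiguously placed contigs.
    Returns (placed contigs sorted by offset, unplaced contigs).
    """
    ref_index = _kmer_index(reference.residues, k)
    per_contig: list[tuple[Contig, list[tuple[int, int, str, str]]]] = []
    unplaced: list[Contig] = []
    for contig in contigs:
        candidates: list[tuple[int, int, str, str]] = []  # (votes, offset, orient, seq)
        for orient, seq in (
            ("as-is", contig.residues),
            ("reverse-complemented", reverse_complement(contig.residues)),
        ):
            votes: Counter[int] = Counter()
            for i in range(0, max(1, len(seq) - k + 1), stride):
                for p in ref_index.get(seq[i : i + k], ()):
                    votes[p - i] += 1
            for offset, n in votes.most_common(2):
                candidates.append((n, offset, orient, seq))
        if not candidates:
            unplaced.append(Contig(contig.id, contig.residues))
            continue
        best_votes = max(c[0] for c in candidates)
        candidates = [c for c in candidates if c[0] >= 0.8 * best_votes]
        per_contig.append((contig, candidates))

    def span(offset: int, seq: str) -> tuple[int, int]:
        return offset, offset + len(seq)

    anchors = [
        span(c[1][0][1], c[1][0][3]) for c in per_contig if len(c[1]) == 1
    ]

    def adjacency(cand) -> int:
        s0, e0 = span(cand[1], cand[3])
        score = 0
        for s1, e1 in anchors:
            ovl = min(e0, e1) - max(s0, s1)
            if 0 < ovl < min(e0 - s0, e1 - s1):  # overlap but not containment
                score += min(ovl, 500)
        return score

    placed: list[Contig] = []
    for contig, candidates in per_contig:
        if len(candidates) > 1:
            candidates.sort(key=lambda c: (-adjacency(c), -c[0]))
        _, offset, orient, seq = candidates[0]
        placed.append(Contig(contig.id, seq, orient, offset))
    placed.sort(key=lambda c: c.ref_offset)
    return placed, unplaced


def stitch_contigs(
    ordered: list[Contig],
    min_overlap: int = 50,
    max_dissimilarity: float = 0.10,
    shift_search: int = 10,
) -> tuple[list[NucleotideSequence], StitchReport]:
    """Merge adjacent positioned contigs whose predicted end overlap is at
    least ``min_overlap`` nt with mismatch fraction below ``max_dissimilarity``.

    Overlap consensus keeps the earlier (left) contig's bases.  Adjacencies
    without a qualifying overlap start a new segment; contigs fully contained
    in the previous one are dropped with a warning.  Returns the stitched
    segments (a single element when everything merged) and a report.
    """
    report = StitchReport()
    if not ordered:
        raise ValueError("no contigs to stitch")
    segments: list[list] = []  # [seq_str, start_offset, last_contig_id]
    for c in ordered:
        if c.ref_offset is None:
            raise ValueError(f"contig {c.id} has no reference offset")
        if not segments:
            segments.append([c.residues, c.ref_offset, c.id])
            continue
        seg = segments[-1]
        seg_end = seg[1] + len(seg[0])
        if c.ref_offset + len(c) <= seg_end:
            warnings.warn(f"contig {c.id} contained within assembly; dropped")
            report.dropped.append(c.id)
            continue
        predicted = seg_end - c.ref_offset
        merged = False
        if predicted >= min_overlap:
            best: tuple[int, int, int] | None = None  # (mm, shift, ovl)
            for shift in range(-shift_search, shift_search + 1):
                ovl = predicted + shift
                if ovl < min_overlap or ovl > min(len(seg[0]), len(c)):
                    continue
                limit = int(max_dissimilarity * ovl)
                mm = _count_mismatches(seg[0][-ovl:], c.residues[:ovl], limit)
                if mm / ovl < max_dissimilarity and (best is None or mm < best[0]):
                    best = (mm, shift, ovl)
            if best is not None:
                mm, _shift, ovl = best
                seg[0] = seg[0] + c.residues[ovl:]
                report.merges.append((seg[2], c.id, ovl, mm))
                seg[2] = c.id
                merged = True
        if not merged:
            report.gaps.append((seg[2], c.id))
            segments.append([c.residues, c.ref_offset, c.id])
    out = [
        NucleotideSequence(f"segment_{i}", s[0]) for i, s in enumerate(segments)
    ]
    return out, report


# ---------------------------------------------------------------------------
# read placement and depth
# ---------------------------------------------------------------------------


def place_reads(
    pairs: list[tuple[QualityRead, QualityRead]],
    target: NucleotideSequence,
    k: int = 31,
    max_mismatch_frac: float = 0.10,
) -> tuple[list[Placement], np.ndarray]:
    """Place every mate on ``target`` by exact k-mer seeding plus ungapped
    extension; all equally-good placements are kept (multi-mapping), which is
    what makes a single-copy IR draft show the 2x coverage signal.

    Returns the placements and a per-position depth profile.
    """
    L = len(target)
    reads = [m for pair in pairs for m in pair if m is not None]
    pad = max((len(r) for r in reads), default=0)
    ext = target.residues + (target.residues[:pad] if target.circular else "")
    index = _kmer_index(target.residues, k)
    placements: list[Placement] = []
    depth = np.zeros(L, dtype=np.int64)
    for read in reads:
        n = len(read)
        if n < k:
            continue
        limit = int(max_mismatch_frac * n)
        best_mm = limit + 1
        best: list[tuple[int, str, str, int]] = []
        for strand, seq in (
            ("+", read.residues),
            ("-", reverse_complement(read.residues)),
        ):
            probes = {0, (n - k) // 2, n - k}
            offsets = set()
            for i in probes:
                for p in index.get(seq[i : i + k], ()):
                    off = (p - i) % L if target.circular else p - i
                    offsets.add(off)
            for off in offsets:
                if off < 0 or off + n > len(ext):
                    continue
                mm = _count_mismatches(seq, ext[off : off + n], best_mm)
                if mm < best_mm:
                    best_mm = mm
                    best = [(off, strand, seq, mm)]
                elif mm == best_mm and mm <= limit:
                    if not any(b[0] == off and b[1] == strand for b in best):
                        best.append((off, strand, seq, mm))
        if best_mm > limit:
            continue
        for off, strand, seq, mm in best:
            placements.append(Placement(read.id, read.mate, off, n, strand, mm, seq))
            end = off + n
            if end <= L:
                depth[off:end] += 1
            else:
                depth[off:] += 1
                depth[: end - L] += 1
    return placements, depth


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------


def _smooth(depth: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return depth.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(depth.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(depth)]
    return out


def detect_ir_by_coverage(
    depth: np.ndarray,
    ratio: float = 2.0,
    tol: float = 0.30,
    window: int = 500,
    min_len: int = 1000,
    read_len: int | None = None,
) -> tuple[int, int] | None:
    """Find the IR on a one-copy draft as the contiguous region whose
    windowed depth is about ``ratio`` times the depth elsewhere.

    Boundary refinement: coverage climbs linearly from 1x to 2x over a ramp
    one read length wide starting at the true boundary (reads spanning the
    missing-copy junction do not place), so the 1.5x-baseline crossing sits
    half a ramp inside the repeat.  The crossing is located on symmetrically
    smoothed depth (which preserves the mid-ramp crossing of a linear ramp)
    and pushed outward by half the ramp width, taken from ``read_len`` when
    given and otherwise estimated from the 1.25x/1.75x crossing distance.
    Returns ``None`` when no elevated region of at least ``min_len`` exists.
    """
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    if n < 2 * min_len or depth.max() == 0:
        return None
    smooth = _smooth(depth, window)
    median = float(np.median(depth))
    if median == 0:
        return None
    mask = smooth >= 1.5 * median
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    candidates = []
    for s, e in runs:
        if e - s < min_len:
            continue
        outside = np.concatenate([depth[:s], depth[e:]])
        med_out = float(np.median(outside)) if len(outside) else median
        if med_out == 0:
            continue
        if float(depth[s:e].mean()) >= ratio * med_out * (1 - tol):
            candidates.append((e - s, s, e, med_out))
    if not candidates:
        return None
    _, s, e, med_out = max(candidates)
    smooth_w = 301
    ref = _smooth(depth, smooth_w)

    def crossing(anchor: int, level: float, direction: int) -> int:
        """Outermost index near ``anchor`` where ref crosses ``level`` moving
        outward in ``direction`` (-1 left edge, +1 right edge)."""
        i = anchor
        thr = level * med_out
        if direction < 0:
            while i > 0 and ref[i - 1] >= thr:
                i -= 1
            while i < n and ref[i] < thr:
                i += 1
        else:
            while i < n and ref[i] >= thr:
                i += 1
            while i > 0 and ref[i - 1] < thr:
                i -= 1
        return i

    def boundary(anchor: int, direction: int) -> int:
        mid = crossing(anchor, 1.5, direction)
        if read_len is not None:
            ramp = float(read_len)
        else:
            # smoothing widens the apparent ramp by the window width:
            # crossings of 1.25x/1.75x sit (R + W)/2 apart on a linear ramp
            lo = crossing(mid, 1.25, direction)
            hi = crossing(mid, 1.75, direction)
            ramp = max(0.0, 2 * abs(hi - lo) - smooth_w)
        return _fit_ramp_boundary(ref, med_out, mid, ramp, smooth_w, direction)

    def _fit_ramp_boundary(ref, base, mid, ramp, W, direction) -> int:
        """Least-squares fit of the box-smoothed 1x->2x coverage ramp to the
        smoothed depth around ``mid``; baseline and amplitude are absorbed by
        linear regression so only the ramp start (the repeat boundary) is
        scanned.  Returns the fitted boundary."""

        def F(u):  # antiderivative of clip(u / max(ramp, 1), 0, 1)
            r = max(ramp, 1.0)
            u = np.asarray(u, dtype=float)
            return np.where(u < 0, 0.0, np.where(u <= r, u * u / (2 * r), u - r / 2))

        half_w = int((max(ramp, 1) + W) / 2 + 200)
        xs = np.arange(max(0, mid - half_w), min(len(ref), mid + half_w))
        if len(xs) < 50:
            return mid + int(direction * ramp / 2)
        obs = ref[xs].astype(float)
        # the 1.5x crossing sits half a ramp inside the repeat
        guess = mid + direction * int(round(ramp / 2))
        best_b, best_sse = guess, np.inf
        for b in range(guess - 150, guess + 151):
            d = (xs - b).astype(float) if direction < 0 else (b - xs).astype(float)
            f = (F(d + W / 2) - F(d - W / 2)) / W
            # regress obs on [1, f]
            fm = f - f.mean()
            om = obs - obs.mean()
            denom = float(fm @ fm)
            beta = float(fm @ om) / denom if denom > 0 else 0.0
            resid = om - beta * fm
            sse = float(resid @ resid)
            if sse < best_sse:
                best_b, best_sse = b, sse
        return best_b

    def changepoint(b0: int, direction: int) -> int:
        """Refine on raw depth *increments*: doubled-read starts switch the
        mean increment from ~0 to the per-position start rate exactly at the
        boundary (left edge; mirrored on the right).  Start/end events are
        independent, so a two-mean changepoint fit is sharp (a few bp at
        plastome coverages)."""
        R = int(read_len) if read_len else 0
        half = 250 + R
        lo, hi = max(1, b0 - half), min(n, b0 + half)
        xs = np.arange(lo, hi)
        if len(xs) < 100:
            return b0
        d = (depth[xs] - depth[xs - 1]).astype(float)
        if direction > 0:  # descending edge: mirror so the step is upward
            d = -d[::-1]
        best_k, best_sse = None, np.inf
        lam = med_out / read_len if read_len else None
        if lam is not None:
            # doubled-read starts form a square pulse of known height
            # (depth / read length) and width (read length) beginning at the
            # boundary: starts jump at b, their ends cancel them at b + R.
            # Matching the whole pulse uses both pulse edges.
            csum = np.concatenate([[0.0], np.cumsum(d)])
            for k in range(20, len(d) - 20):
                k2 = min(k + R, len(d))
                in_pulse = csum[k2] - csum[k]
                width = k2 - k
                # SSE difference vs the all-zero model, expanded
                sse = -2 * lam * in_pulse + width * lam * lam
                if sse < best_sse:
                    best_k, best_sse = k, sse
        else:
            for k in range(20, len(d) - 20):
                left_seg, right_seg = d[:k], d[k:]
                mu0, mu1 = left_seg.mean(), right_seg.mean()
                if mu1 <= mu0:
                    continue
                sse = float(
                    ((left_seg - mu0) ** 2).sum() + ((right_seg - mu1) ** 2).sum()
                )
                if sse < best_sse:
                    best_k, best_sse = k, sse
        if best_k is None:
            return b0
        # increment at index k belongs to position xs[k]; a read starting at
        # b first raises depth[b], i.e. d-index of position b
        if direction < 0:
            return int(xs[best_k])
        return int(xs[len(d) - best_k - 1])

    left = max(0, changepoint(boundary(s, -1), -1))
    right = min(n, changepoint(boundary(e, +1), +1))
    if right - left < min_len:
        return None
    return left, right


def find_inverted_repeat(
    seq: NucleotideSequence,
    min_len: int = 1000,
    min_identity: float = 0.99,
    k: int = 31,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Locate the two inverted-repeat copies by seeding the sequence against
    its own reverse complement and extending ungapped.

    Returns the (lower-coordinate, higher-coordinate) interval pair, or
    ``None`` when no reverse-complementary repeat of at least ``min_len`` at
    ``min_identity`` exists.
    """
    s = seq.residues
    L = len(s)
    if L < 2 * min_len:
        return None
    rc = reverse_complement(s)
    rc_index = _kmer_index(rc, k)
    # a k-mer at i matching rc at p corresponds to genomic interval
    # [L - p - k, L - p) being the reverse complement of [i, i + k).
    # Positions x and y pair when x + y == m with m = i + j + k - 1.
    diagonals: dict[int, list[int]] = defaultdict(list)
    for i in range(0, L - k + 1):
        for p in rc_index.get(s[i : i + k], ()):
            j = L - p - k
            if j - i >= k:  # keep i < j, skip palindrome self-hits
                diagonals[i + j + k - 1].append(i)
    if not diagonals:
        return None
    comp = str.maketrans("ACGT", "TGCA")

    def pairs_ok(x: int) -> bool:
        """Does position x pair with its partner m - x?"""
        y = m_current - x
        return 0 <= y < L and s[x] == s[y].translate(comp)

    m_current = 0

    def extend(m: int, seeds: list[int]) -> tuple[int, int, int, int] | None:
        nonlocal m_current
        m_current = m
        a, b = min(seeds), max(seeds) + k  # lower interval [a, b)
        budget = int((1 - min_identity) * (b - a)) + 5

        def continues(x: int, step: int) -> bool:
            """Mismatch at x: does the repeat genuinely continue past it?
            Require >= 7 of the next 8 positions to pair."""
            hits = 0
            for d in range(1, 9):
                y = x + step * d
                if not (0 <= y < L) or not (m - y > max(b - 1, y) if step < 0 else m - y > y):
                    return False
                if pairs_ok(y):
                    hits += 1
            return hits >= 7

        # extend left: step over a mismatch only when the repeat continues
        while a > 0 and m - (a - 1) > b - 1:
            if pairs_ok(a - 1):
                a -= 1
            elif budget > 0 and continues(a - 1, -1):
                budget -= 1
                a -= 1
            else:
                break
        # extend right; keep intervals disjoint (partner of b is m - b)
        while b < L and m - b > b:
            if pairs_ok(b):
                b += 1
            elif budget > 0 and continues(b, +1):
                budget -= 1
                b += 1
            else:
                break
        # never end on a mismatch
        while b > a and not pairs_ok(a):
            a += 1
        while b > a and not pairs_ok(b - 1):
            b -= 1
        j0, j1 = m - b + 1, m - a + 1  # partner interval [j0, j1)
        if b - a < min_len or j0 < b or j1 > L:
            return None
        mm = sum(1 for x in range(a, b) if not pairs_ok(x))
        if 1 - mm / (b - a) < min_identity:
            return None
        return a, b, j0, j1

    best: tuple[int, int, int, int] | None = None
    # try diagonals in order of decreasing seed support
    for m, seeds in sorted(diagonals.items(), key=lambda kv: -len(kv[1]))[:10]:
        if len(seeds) * k < min_len // 2:
            continue
        hit = extend(m, seeds)
        if hit and (best is None or hit[1] - hit[0] > best[1] - best[0]):
            best = hit
    if best is None:
        return None
    a, b, j0, j1 = best
    return (a, b), (j0, j1)


# ---------------------------------------------------------------------------
# completion, ambiguity resolution, partition
# ---------------------------------------------------------------------------


def match_ir_contig(
    draft: NucleotideSequence,
    contigs: list[Contig],
    candidate: tuple[int, int],
    slack: int = 200,
) -> tuple[int, int] | None:
    """Refine a coverage-identified IR candidate to exact boundaries by
    matching it against an assembled contig.

    A contig (either orientation) that occurs verbatim in the draft with
    both ends within ``slack`` bp of the candidate interval defines the IR
    exactly; 100% identity is required for this auto-complete path.
    Returns the exact interval or ``None`` (caller should then report)."""
    best: tuple[int, int] | None = None
    for contig in contigs:
        for seq in (contig.residues, reverse_complement(contig.residues)):
            pos = draft.residues.find(seq)
            if pos == -1:
                continue
            iv = (pos, pos + len(seq))
            if abs(iv[0] - candidate[0]) <= slack and abs(iv[1] - candidate[1]) <= slack:
                if best is None or iv[1] - iv[0] > best[1] - best[0]:
                    best = iv
    return best


def complete_assembly(
    draft: NucleotideSequence, ir_interval: tuple[int, int]
) -> NucleotideSequence:
    """Append the reverse complement of the single IR copy after the SSC,
    turning an LSC-IRb-SSC draft into the complete LSC-IRb-SSC-IRa genome."""
    s, e = ir_interval
    if not (0 <= s < e <= len(draft)):
        raise ValueError(f"IR interval [{s},{e}) out of bounds")
    completed = draft.residues + reverse_complement(draft.residues[s:e])
    return NucleotideSequence(draft.id, completed, circular=True)


def resolve_ambiguities(
    assembly: NucleotideSequence,
    placements: list[Placement],
    min_depth: int = 3,
) -> tuple[NucleotideSequence, list[int]]:
    """Replace IUPAC ambiguity positions by the strict-majority base among
    covering read bases; positions without a strict majority (or covered by
    fewer than ``min_depth`` reads) stay ambiguous and are reported."""
    seq = list(assembly.residues)
    L = len(seq)
    amb_positions = [i for i, c in enumerate(seq) if c not in "ACGT"]
    unresolved: list[int] = []
    if not amb_positions:
        return assembly, unresolved
    amb_set = set(amb_positions)
    votes: dict[int, Counter] = {i: Counter() for i in amb_positions}
    for pl in placements:
        for idx in range(pl.length):
            pos = (pl.start + idx) % L
            if pos in amb_set:
                base = pl.oriented[idx]
                if base in "ACGT":
                    votes[pos][base] += 1
    for pos in amb_positions:
        counter = votes[pos]
        total = sum(counter.values())
        if total < min_depth:
            unresolved.append(pos)
            continue
        base, n = counter.most_common(1)[0]
        if n * 2 > total:
            seq[pos] = base
        else:
            unresolved.append(pos)
    return (
        NucleotideSequence(assembly.id, "".join(seq), assembly.circular),
        unresolved,
    )


def partition_quadripartite(
    seq: NucleotideSequence, ir_pair: tuple[tuple[int, int], tuple[int, int]]
) -> QuadripartitePartition:
    """Label the four regions of a finished plastome given its IR intervals.

    The longer single-copy stretch between the IRs becomes the LSC; region
    names follow the canonical circular order LSC-IRb-SSC-IRa."""
    (a0, a1), (b0, b1) = sorted(ir_pair)
    L = len(seq)
    if a1 > b0:
        raise ValueError("IR intervals overlap")
    inner = (a1, b0)  # between the two IRs
    outer = (b1 % L, a0)  # wraps the origin unless b1 == L
    inner_len = inner[1] - inner[0]
    outer_len = (a0 - (b1 % L)) % L
    if inner_len >= outer_len:
        # inner single-copy region is the LSC
        return QuadripartitePartition(
            lsc=inner, irb=(b0, b1), ssc=outer, ira=(a0, a1), genome_length=L
        )
    return QuadripartitePartition(
        lsc=outer, irb=(a0, a1), ssc=inner, ira=(b0, b1), genome_length=L
    )


# ---------------------------------------------------------------------------
# read extraction and statistics
# ---------------------------------------------------------------------------


def extract_plastid_reads(
    pairs: list[tuple[QualityRead, QualityRead]],
    placements: list[Placement],
) -> tuple[list[tuple[QualityRead, QualityRead]], int]:
    """Keep pairs where at least one mate placed on the assembly."""
    mapped_ids = {p.read_id for p in placements}
    kept = [pair for pair in pairs if pair[0].id in mapped_ids]
    return kept, len(kept)


def assembly_stats(
    placements: list[Placement],
    depth: np.ndarray,
    pairs: list[tuple[QualityRead, QualityRead]],
) -> AssemblyStats:
    """Mapping and coverage statistics of a finished assembly."""
    mapped_ids = {p.read_id for p in placements}
    n_pairs = len(pairs)
    mapped_pairs = [p for p in pairs if p[0].id in mapped_ids]
    n_mapped = len(mapped_pairs)
    mean_read_len = (
        float(np.mean([len(a) + len(b) for a, b in mapped_pairs]))
        if mapped_pairs
        else float("nan")
    )
    depth = np.asarray(depth)
    return AssemblyStats(
        n_mapped=n_mapped,
        p_mapped=n_mapped / n_pairs if n_pairs else 0.0,
        mean_read_len=mean_read_len,
        mean_depth=float(depth.mean()),
        p_ge_20x=float((depth >= 20).mean()),
        p_ge_50x=float((depth >= 50).mean()),
        p_ge_100x=float((depth >= 100).mean()),
    )


def contig_stats(contigs: list[Contig], min_len: int = 1000) -> ContigStats:
    """N50/L50 statistics over contigs of at least ``min_len`` bp."""
    lengths = sorted((len(c) for c in contigs if len(c) >= min_len), reverse=True)
    if not lengths:
        raise ValueError(f"no contigs of length >= {min_len}")
    total = sum(lengths)
    acc = 0
    for i, ln in enumerate(lengths, 1):
        acc += ln
        if 2 * acc >= total:
            return ContigStats(
                n_contigs=len(lengths), largest=lengths[0], total=total, n50=ln, l50=i
            )
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# depth profile I/O (so external-mapper depth can be swapped in)
# ---------------------------------------------------------------------------


def write_depth_tsv(depth: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(np.asarray(depth)):
            fh.write(f"{i}\t{int(d)}\n")


def read_depth_tsv(path) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                _, d = line.split("\t")
                vals.append(int(d))
    return np.array(vals, dtype=np.int64)
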