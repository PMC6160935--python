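"""Paired-read preparation: ordered R1/R2 intersection, 3' quality trimming
with a minimum-length filter, adapter removal, and read-loss accounting.

The quality step trims each read at its 3' end back to the last base with
Phred quality >= ``min_q`` (default 30), discards reads shorter than
``min_len`` afterwards, and re-synchronizes the pairing (both mates must
survive).  Header matching strips both ``/1``-``/2`` and Casava
``1:N:0:...`` mate-suffix dialects; sorting is plain lexicographic on the
stripped header.
"""

from __future__ import annotations

from dataclasses import dataclass

from plastokit.seqio import QualityRead

Pair = tuple[QualityRead, QualityRead]


@dataclass
class ReadSetReport:
    n_before: int
    n_after: int
    n_orphans_removed: int = 0
    mean_pair_length: float | None = None

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise ValueError("n_after exceeds n_before")
        if min(self.n_before, self.n_after, self.n_orphans_removed) < 0:
            raise ValueError("negative counts")

    def as_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_orphans_removed": self.n_orphans_removed,
            "mean_pair_length": self.mean_pair_length,
        }


def strip_mate_suffix(header: str) -> str:
    """Strip ``/1``, ``/2`` and Casava ``1:N:0:...``-style mate suffixes."""
    token = header.split()[0] if header.split() else header
    if token.endswith("/1") or token.endswith("/2"):
        return token[:-2]
    return token


def paired_intersection(
    r1_reads: list[QualityRead], r2_reads: list[QualityRead]
) -> tuple[list[QualityRead], list[QualityRead], ReadSetReport]:
    """Keep exactly the reads whose stripped ID occurs in both mate files,
    sorted lexicographically by header so R1[i] and R2[i] always pair."""
    maps = []
    for reads, mate in ((r1_reads, "R1"), (r2_reads, "R2")):
        mapping: dict[str, QualityRead] = {}
        for r in reads:
            key = strip_mate_suffix(r.id)
            if key in mapping:
                raise ValueError(f"duplicate read ID {key!r} in {mate} file")
            mapping[key] = r
        maps.append(mapping)
    m1, m2 = maps
    common = sorted(set(m1) & set(m2))
    n_before = len(r1_reads) + len(r2_reads)
    out1 = [m1[k] for k in common]
    out2 = [m2[k] for k in common]
    report = ReadSetReport(
        n_before=n_before,
        n_after=2 * len(common),
        n_orphans_removed=n_before - 2 * len(common),
    )
    return out1, out2, report


def quality_trim_filter(
    pairs: list[Pair], min_q: int = 30, min_len: int = 50
) -> tuple[list[Pair], ReadSetReport]:
    """3'-trim trailing bases with quality < ``min_q``, drop mates shorter
    than ``min_len``, and keep only pairs where both mates survive."""

    def trim(read: QualityRead) -> QualityRead:
        keep = len(read)
        while keep > 0 and read.qualities[keep - 1] < min_q:
            keep -= 1
        return read.trimmed(keep)

    out: list[Pair] = []
    for r1, r2 in pairs:
        t1, t2 = trim(r1), trim(r2)
        if len(t1) >= min_len and len(t2) >= min_len:
            out.append((t1, t2))
    report = ReadSetReport(n_before=len(pairs), n_after=len(out))
    return out, report


def _trim_adapter(read: QualityRead, adapters: list[str], min_overlap: int, max_mismatch: int) -> QualityRead:
    seq = read.residues
    n = len(seq)
    best_cut = n
    for adapter in adapters:
        # internal full-length occurrence: cut from the match position on
        pos = seq.find(adapter)
        if pos != -1:
            best_cut = min(best_cut, pos)
            continue
        # longest suffix of the read matching a prefix of the adapter
        for start in range(max(0, n - len(adapter)), n - min_overlap + 1):
            ovl = n - start
            frag = adapter[:ovl]
            mm = sum(1 for a, b in zip(seq[start:], frag) if a != b)
            if mm <= max_mismatch:
                best_cut = min(best_cut, start)
                break
    return read.trimmed(best_cut) if best_cut < n else read


def adapter_trim(
    pairs: list[Pair],
    adapters: list[str],
    min_overlap: int = 12,
    max_mismatch: int = 1,
) -> list[Pair]:
    """Remove 3' adapter read-through: the longest read suffix matching an
    adapter prefix over >= ``min_overlap`` bases with <= ``max_mismatch``
    mismatches is cut off; full internal adapter hits cut from the hit on."""
    adapters = [a.upper() for a in adapters]
    return [
        (
            _trim_adapter(r1, adapters, min_overlap, max_mismatch),
            _trim_adapter(r2, adapters, min_overlap, max_mismatch),
        )
        for r1, r2 in pairs
    ]


def read_stats(pairs: list[Pair]) -> ReadSetReport:
    """Mean pair length = mean over pairs of len(R1) + len(R2)."""
    n = len(pairs)
    mean = (
        sum(len(r1) + len(r2) for r1, r2 in pairs) / n if n else None
    )
    return ReadSetReport(n_before=n, n_after=n, mean_pair_length=mean)
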