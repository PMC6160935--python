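"""Assembly finishing: positioning, stitching, read placement, IR detection,
completion, ambiguity resolution, partitioning and statistics."""

import numpy as np
import pytest

from plastokit.assemblyfinish import (
    AssemblyStats,
    Contig,
    Placement,
    QuadripartitePartition,
    assembly_stats,
    complete_assembly,
    contig_stats,
    detect_ir_by_coverage,
    extract_plastid_reads,
    find_inverted_repeat,
    match_ir_contig,
    partition_quadripartite,
    place_reads,
    position_contigs,
    read_depth_tsv,
    resolve_ambiguities,
    stitch_contigs,
    write_depth_tsv,
)
from plastokit.seqio import NucleotideSequence, QualityRead, reverse_complement
from plastokit.synth import ReadSimSpec, _random_seq, simulate_reads


def _reads_from(seq, rid="r", mate="R1", q=40):
    return QualityRead(rid, mate, seq, [q] * len(seq))


class TestPositionContigs:
    def test_known_cut_positions_recovered(self, small_plastome):
        genome, part = small_plastome
        s = genome.sequence.residues
        cuts = [(0, 5000), (4900, 9000), (8900, len(s))]
        contigs = [
            Contig("c0", s[cuts[0][0] : cuts[0][1]]),
            Contig("c1", reverse_complement(s[cuts[1][0] : cuts[1][1]])),
            Contig("c2", s[cuts[2][0] : cuts[2][1]]),
        ]
        placed, unplaced = position_contigs(contigs, genome.sequence)
        assert not unplaced
        assert [(c.ref_offset, c.orientation) for c in placed] == [
            (0, "as-is"),
            (4900, "reverse-complemented"),
            (8900, "as-is"),
        ]

    def test_identical_contig_offset_zero(self, small_plastome):
        genome, _ = small_plastome
        placed, _ = position_contigs(
            [Contig("whole", genome.sequence.residues)], genome.sequence
        )
        assert placed[0].ref_offset == 0 and placed[0].orientation == "as-is"

    def test_unrelated_contig_unplaced(self, small_plastome):
        genome, _ = small_plastome
        rng = np.random.default_rng(99)
        junk = _random_seq(rng, 2000, 0.5)
        placed, unplaced = position_contigs([Contig("junk", junk)], genome.sequence)
        assert not placed and [c.id for c in unplaced] == ["junk"]


class TestStitchContigs:
    def test_exact_overlap_merges(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 500, 0.4)
        a = Contig("a", s[:300], ref_offset=0)
        b = Contig("b", s[240:], ref_offset=240)
        segments, rep = stitch_contigs([a, b])
        assert len(segments) == 1
        assert len(segments[0]) == 300 + 260 - 60
        assert segments[0].residues == s
        assert rep.merges == [("a", "b", 60, 0)]

    def test_dissimilar_overlap_not_merged(self):
        rng = np.random.default_rng(1)
        s = _random_seq(rng, 400, 0.4)
        a = Contig("a", s[:250], ref_offset=0)
        # corrupt 6 of the 50 overlap bases (12% > 10%)
        tail = list(s[200:])
        for i in (3, 11, 19, 27, 35, 43):
            tail[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[i]]
        b = Contig("b", "".join(tail), ref_offset=200)
        segments, rep = stitch_contigs([a, b])
        assert len(segments) == 2 and rep.gaps == [("a", "b")]

    def test_contained_contig_dropped(self):
        rng = np.random.default_rng(2)
        s = _random_seq(rng, 600, 0.4)
        a = Contig("a", s[:500], ref_offset=0)
        b = Contig("b", s[100:300], ref_offset=100)
        with pytest.warns(UserWarning):
            segments, rep = stitch_contigs([a, b])
        assert len(segments) == 1 and rep.dropped == ["b"]

    def test_three_contigs_reproduce_draft(self, small_plastome):
        genome, part = small_plastome
        draft = genome.sequence.residues[: part.ssc[1]]
        L1, L2 = part.irb
        contigs = [
            Contig("lsc", draft[: L1 + 100], ref_offset=0),
            Contig("ir", draft[L1:L2], ref_offset=L1),
            Contig("ssc", draft[L2 - 100 :], ref_offset=L2 - 100),
        ]
        segments, _ = stitch_contigs(contigs)
        assert len(segments) == 1 and segments[0].residues == draft


class TestPlaceReads:
    def test_ir_read_multiplicity(self, small_plastome):
        genome, part = small_plastome
        s = genome.sequence.residues
        ir_read = s[part.irb[0] + 500 : part.irb[0] + 600]
        draft = NucleotideSequence("draft", s[: part.ssc[1]])  # one IR copy
        complete = genome.sequence
        pairs = [(_reads_from(ir_read, "x", "R1"), _reads_from(ir_read, "x", "R2"))]
        pl_draft, _ = place_reads([(pairs[0][0], pairs[0][0])], draft)
        pl_full, _ = place_reads([(pairs[0][0], pairs[0][0])], complete)
        # each mate: 1 placement on the one-copy draft, 2 on the full genome
        assert len(pl_draft) == 2 and len(pl_full) == 4

    def test_zero_reads_zero_profile(self, small_plastome):
        genome, _ = small_plastome
        placements, depth = place_reads([], genome.sequence)
        assert not placements and not depth.any()

    def test_uniform_coverage_recovered(self, small_plastome):
        genome, _ = small_plastome
        r1, r2, _ = simulate_reads(
            genome.sequence,
            ReadSimSpec(coverage=100, error_rate=0.0, adapter_rate=0.0,
                        orphan_rate=0.0, seed=8),
        )
        genome, part = small_plastome
        _, depth = place_reads(list(zip(r1, r2)), genome.sequence)
        # multi-mapping doubles IR depth; judge on the LSC interior
        lsc_mean = float(depth[part.lsc[0] + 500 : part.lsc[1] - 500].mean())
        assert abs(lsc_mean - 100) / 100 < 0.05


class TestDetectIrByCoverage:
    def test_constructed_step_profile(self):
        depth = np.full(10_000, 100)
        depth[5000:7500] = 200
        iv = detect_ir_by_coverage(depth, min_len=1000)
        assert iv is not None
        assert abs(iv[0] - 5000) <= 5 and abs(iv[1] - 7500) <= 5

    def test_flat_profile_empty(self):
        assert detect_ir_by_coverage(np.full(10_000, 120), min_len=1000) is None

    def test_simulated_draft_within_25bp(self, small_plastome):
        genome, part = small_plastome
        draft = NucleotideSequence(
            "draft", genome.sequence.residues[: part.ssc[1]]
        )
        r1, r2, _ = simulate_reads(
            genome.sequence,
            ReadSimSpec(coverage=200, error_rate=0.0, adapter_rate=0.0,
                        orphan_rate=0.0, seed=9),
        )
        _, depth = place_reads(list(zip(r1, r2)), draft, max_mismatch_frac=0.02)
        iv = detect_ir_by_coverage(depth, min_len=1000, read_len=300)
        assert iv is not None
        assert abs(iv[0] - part.irb[0]) <= 25
        assert abs(iv[1] - part.irb[1]) <= 25


class TestFindInvertedRepeat:
    def test_constructed_repeat_recovered(self):
        rng = np.random.default_rng(3)
        x = _random_seq(rng, 4000, 0.4)
        p = _random_seq(rng, 2500, 0.4)
        y = _random_seq(rng, 1500, 0.4)
        seq = NucleotideSequence("t", x + p + y + reverse_complement(p), circular=True)
        hit = find_inverted_repeat(seq, min_len=1000)
        # allow the rare chance extension when junction bases happen to pair
        assert hit is not None
        (a0, a1), (b0, b1) = hit
        assert abs(a0 - 4000) <= 2 and abs(a1 - 6500) <= 2
        assert abs(b0 - 8000) <= 2 and abs(b1 - 10500) <= 2

    def test_no_repeat_returns_none(self):
        rng = np.random.default_rng(4)
        seq = NucleotideSequence("t", _random_seq(rng, 8000, 0.4), circular=True)
        assert find_inverted_repeat(seq, min_len=1000) is None

    def test_synthetic_plastome_exact(self, small_plastome):
        genome, part = small_plastome
        hit = find_inverted_repeat(genome.sequence, min_len=1000)
        assert hit == (part.irb, part.ira)


class TestCompletionAndPartition:
    def test_completed_length_arithmetic(self, small_plastome):
        genome, part = small_plastome
        draft = NucleotideSequence("d", genome.sequence.residues[: part.ssc[1]])
        completed = complete_assembly(draft, part.irb)
        assert len(completed) == len(draft) + part.ir_length

    def test_completed_equals_simulated_genome(self, small_plastome):
        genome, part = small_plastome
        draft = NucleotideSequence("d", genome.sequence.residues[: part.ssc[1]])
        completed = complete_assembly(draft, part.irb)
        assert completed.residues == genome.sequence.residues
        hit = find_inverted_repeat(completed, min_len=1000)
        partition = partition_quadripartite(completed, hit)
        assert (
            partition.lsc_length + partition.ssc_length + 2 * partition.ir_length
            == len(completed)
        )
        assert partition.ir_length == part.ir_length

    def test_out_of_bounds_interval_is_error(self, small_plastome):
        genome, _ = small_plastome
        with pytest.raises(ValueError):
            complete_assembly(genome.sequence, (100, len(genome.sequence) + 5))

    def test_overlapping_irs_rejected(self, small_plastome):
        genome, _ = small_plastome
        with pytest.raises(ValueError):
            partition_quadripartite(genome.sequence, ((100, 3000), (2000, 5000)))

    def test_ir_equality_invariant(self, small_plastome):
        genome, part = small_plastome
        s = genome.sequence.residues
        irb = s[part.irb[0] : part.irb[1]]
        ira = s[part.ira[0] : part.ira[1]]
        assert ira == reverse_complement(irb)

    def test_match_ir_contig_refines_candidate(self, small_plastome):
        genome, part = small_plastome
        draft = NucleotideSequence("d", genome.sequence.residues[: part.ssc[1]])
        ir_contig = Contig(
            "ir", reverse_complement(draft.residues[part.irb[0] : part.irb[1]])
        )
        fuzzy = (part.irb[0] - 40, part.irb[1] + 15)
        assert match_ir_contig(draft, [ir_contig], fuzzy) == part.irb


class TestResolveAmbiguities:
    def _placement(self, base, pos, rid):
        return Placement(rid, "R1", pos, 1, "+", 0, base)

    def test_strict_majority_resolves(self):
        seq = NucleotideSequence("a", "ACGRACGT")
        placements = [self._placement(b, 3, f"r{i}")
                      for i, b in enumerate("AAAG")]
        fixed, unresolved = resolve_ambiguities(seq, placements)
        assert fixed.residues == "ACGAACGT" and not unresolved

    def test_tie_left_ambiguous_and_reported(self):
        seq = NucleotideSequence("a", "ACGRACGT")
        placements = [self._placement(b, 3, f"r{i}") for i, b in enumerate("AAGG")]
        fixed, unresolved = resolve_ambiguities(seq, placements)
        assert fixed.residues[3] == "R" and unresolved == [3]

    def test_simulated_ambiguities_all_restored(self, small_plastome):
        # ambiguities arise in the one-IR draft; completing the assembly
        # duplicates any IR ambiguity into both copies, as in the real
        # workflow, so reads from either copy tie and cover both
        genome, part = small_plastome
        rng = np.random.default_rng(10)
        draft_chars = list(genome.sequence.residues[: part.ssc[1]])
        pos = sorted(
            int(p) for p in rng.choice(len(draft_chars), 10, replace=False)
        )
        for p in pos:
            draft_chars[p] = "R" if draft_chars[p] in "AG" else "Y"
        noisy_draft = NucleotideSequence("n", "".join(draft_chars))
        noisy = complete_assembly(noisy_draft, part.irb)
        r1, r2, _ = simulate_reads(
            genome.sequence,
            ReadSimSpec(coverage=100, error_rate=0.0, adapter_rate=0.0,
                        orphan_rate=0.0, seed=10),
        )
        placements, _ = place_reads(list(zip(r1, r2)), noisy)
        fixed, unresolved = resolve_ambiguities(noisy, placements)
        assert not unresolved
        assert fixed.residues == genome.sequence.residues


class TestStatistics:
    def test_n50_l50_worked_example(self):
        contigs = [Contig(f"c{i}", "A" * n) for i, n in enumerate((5, 4, 3, 2, 1))]
        st = contig_stats(contigs, min_len=0)
        assert (st.total, st.n50, st.l50) == (15, 4, 2)

    def test_single_contig(self):
        st = contig_stats([Contig("c", "A" * 1200)])
        assert st.n50 == 1200 and st.l50 == 1

    def test_empty_after_filter_is_error(self):
        with pytest.raises(ValueError):
            contig_stats([Contig("c", "A" * 10)], min_len=1000)

    def test_depth_threshold_fractions(self):
        depth = np.full(100, 60)
        pairs = [(_reads_from("ACGT" * 10, "a", "R1"), _reads_from("ACGT" * 10, "a", "R2"))]
        placements = [Placement("a", "R1", 0, 40, "+", 0, "ACGT" * 10)]
        st = assembly_stats(placements, depth, pairs)
        assert st.p_ge_50x == 1.0 and st.p_ge_100x == 0.0
        assert st.p_ge_20x >= st.p_ge_50x >= st.p_ge_100x

    def test_threshold_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            AssemblyStats(1, 0.5, 300.0, 50.0, 0.3, 0.6, 0.1)

    def test_extract_plastid_reads(self):
        pairs = [
            (_reads_from("ACGT" * 10, "a", "R1"), _reads_from("ACGT" * 10, "a", "R2")),
            (_reads_from("ACGT" * 10, "b", "R1"), _reads_from("ACGT" * 10, "b", "R2")),
        ]
        placements = [Placement("a", "R1", 0, 40, "+", 0, "ACGT" * 10)]
        kept, n = extract_plastid_reads(pairs, placements)
        assert n == 1 and kept[0][0].id == "a"

    def test_depth_tsv_round_trip(self, tmp_path):
        depth = np.array([0, 5, 17, 3], dtype=np.int64)
        p = tmp_path / "depth.tsv"
        write_depth_tsv(depth, p)
        assert (read_depth_tsv(p) == depth).all()
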