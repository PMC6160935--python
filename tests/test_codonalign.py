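"""Codon-aware alignment: extraction, protein-guided MSA, back-translation,
concatenation, gap-column removal and pairwise statistics."""

import pytest

from plastokit.codonalign import (
    GeneAlignment,
    Supermatrix,
    align_gene,
    alignment_stats,
    concatenate,
    extract_cds_groups,
    read_alignment_fasta,
    remove_gap_columns,
    write_supermatrix_fasta,
    write_supermatrix_nexus,
)
from plastokit.seqio import (
    AnnotatedGenome,
    GenomeFeature,
    NucleotideSequence,
    reverse_complement,
)
from plastokit.synth import mutate_cds_family


def _mini_genome(taxon: str, seq: str, feats) -> AnnotatedGenome:
    return AnnotatedGenome(NucleotideSequence(taxon, seq), feats)


class TestExtractCdsGroups:
    def test_minus_strand_equals_revcomp_of_slice(self):
        cds = "ATGGCAGCATAA"
        seq = "CCCC" + reverse_complement(cds) + "GGGG"
        g = _mini_genome("t1", seq, [GenomeFeature("x", "CDS", "-", [(4, 16)])])
        groups = extract_cds_groups([g])
        assert groups["x"] == [("t1", cds)]

    def test_two_exon_gene_joins_parts(self):
        seq = "ATGAAA" + "TTTT" + "GGGTAA" + "CC"
        g = _mini_genome(
            "t1", seq, [GenomeFeature("x", "CDS", "+", [(0, 6), (10, 16)])]
        )
        assert extract_cds_groups([g])["x"] == [("t1", "ATGAAAGGGTAA")]

    def test_missing_gene_missing_from_group(self, genome_family):
        genomes, _, _ = genome_family
        taxa = sorted(genomes)
        trimmed = []
        for i, t in enumerate(taxa):
            g = genomes[t]
            feats = g.features
            if i == 0:  # drop one gene from the first taxon
                feats = [f for f in feats if f.gene != "rbcL"]
            trimmed.append(AnnotatedGenome(g.sequence, feats))
        groups = extract_cds_groups(trimmed)
        assert len(groups["rbcL"]) == 3

    def test_frameshifted_cds_excluded_with_warning(self):
        g = _mini_genome(
            "t1", "ATGAAAT", [GenomeFeature("x", "CDS", "+", [(0, 7)])]
        )
        with pytest.warns(UserWarning):
            groups = extract_cds_groups([g])
        assert "x" not in groups

    def test_ir_duplicates_collapse_per_taxon(self, small_plastome):
        genome, _ = small_plastome
        groups = extract_cds_groups([genome])
        for gene, members in groups.items():
            assert len(members) == 1, gene


class TestAlignGene:
    def test_identical_sequences_zero_gaps(self):
        ga = align_gene("x", [("a", "ATGGCATAA"), ("b", "ATGGCATAA")])
        assert ga.rows == ["ATGGCATAA", "ATGGCATAA"]
        stats = alignment_stats(Supermatrix(ga.taxa, ga.rows, []))
        assert stats.avg_pairwise_identity == 1.0

    def test_forced_back_translation(self):
        ga = align_gene("x", [("a", "ATGGCA"), ("b", "ATGAAAGCA")])
        assert ga.rows == ["ATG---GCA", "ATGAAAGCA"]

    def test_terminal_stop_restored(self):
        ga = align_gene("x", [("a", "ATGGCATAA"), ("b", "ATGAAAGCATAG")])
        assert ga.rows == ["ATG---GCATAA", "ATGAAAGCATAG"]

    def test_internal_stop_is_error_naming_taxon(self):
        with pytest.raises(ValueError, match="b.*x|x.*b"):
            align_gene("x", [("a", "ATGGCATAA"), ("b", "ATGTAAGCATAA")])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_inframe_indel_families_satisfy_invariants(self, seed):
        import numpy as np

        from plastokit.synth import _random_cds

        rng = np.random.default_rng(seed)
        cds = _random_cds(rng, 80, 0.4)
        family = mutate_cds_family(cds, 4, sub_rate=0.03, indel_rate=0.05, seed=seed)
        group = [(f"t{i}", s) for i, s in enumerate(family)]
        ga = align_gene("x", group)
        width = len(ga.rows[0])
        assert width % 3 == 0
        for (taxon, original), row in zip(group, ga.rows):
            assert len(row) == width
            assert row.replace("-", "") == original  # de-gap round trip
            # every gap run is a codon multiple
            run = 0
            for ch in row + "X":
                if ch == "-":
                    run += 1
                else:
                    assert run % 3 == 0
                    run = 0


class TestConcatenate:
    def _ga(self, gene, taxa, rows):
        return GeneAlignment(gene, taxa, rows)

    def test_widths_and_partitions(self):
        g1 = self._ga("g1", ["a", "b"], ["ATG" * 100, "ATG" * 100])
        g2 = self._ga("g2", ["a", "b"], ["TAA" * 50, "TAA" * 50])
        sm = concatenate([g2, g1])  # order input shuffled; output lexicographic
        assert sm.width == 450
        assert sm.partitions == [("g1", 0, 300), ("g2", 300, 450)]

    def test_missing_taxon_gets_gap_block(self):
        g1 = self._ga("g1", ["a", "b"], ["ATGGCA", "ATGGCA"])
        g2 = self._ga("g2", ["a"], ["TAATAA"])
        sm = concatenate([g1, g2])
        row_b = sm.rows[sm.taxa.index("b")]
        assert row_b == "ATGGCA" + "-" * 6

    def test_width_equals_sum_of_widths(self, genome_family):
        genomes, _, _ = genome_family
        groups = extract_cds_groups(list(genomes.values()))
        gas = [align_gene(g, grp) for g, grp in sorted(groups.items())]
        sm = concatenate(gas)
        assert sm.width == sum(ga.width for ga in gas)


class TestRemoveGapColumns:
    def test_forced_example(self):
        sm = Supermatrix(["a", "b"], ["ATG---GCA", "ATGAAAGCA"], [("g", 0, 9)])
        out, before, after = remove_gap_columns(sm)
        assert out.rows == ["ATGGCA", "ATGGCA"]
        assert before.length == 9 and after.length == 6
        assert out.partitions == [("g", 0, 6)]

    def test_gap_free_input_unchanged(self):
        sm = Supermatrix(["a", "b"], ["ATGGCA", "ATGTCA"], [("g", 0, 6)])
        out, _, _ = remove_gap_columns(sm)
        assert out.rows == sm.rows

    def test_output_never_contains_gaps(self, genome_family):
        genomes, _, _ = genome_family
        taxa = sorted(genomes)
        trimmed = []
        for i, t in enumerate(taxa):
            g = genomes[t]
            feats = [f for f in g.features if not (i == 0 and f.gene == "psbA")]
            trimmed.append(AnnotatedGenome(g.sequence, feats))
        groups = extract_cds_groups(trimmed)
        sm = concatenate([align_gene(g, grp) for g, grp in groups.items()])
        out, before, after = remove_gap_columns(sm)
        assert all("-" not in r for r in out.rows)
        # removing all-gap-containing columns can only raise identity here
        assert after.avg_pairwise_identity >= before.avg_pairwise_identity


class TestAlignmentStats:
    def test_identical_pair(self):
        s = alignment_stats(Supermatrix(["a", "b"], ["ACGT", "ACGT"], []))
        assert s.avg_pairwise_identity == 1.0
        assert s.pair_differences[("a", "b")] == 0

    def test_gap_column_counts_against_identity_not_difference(self):
        s = alignment_stats(Supermatrix(["a", "b"], ["AC-G", "ACTG"], []))
        assert s.pair_identity[("a", "b")] == pytest.approx(3 / 4)
        assert s.pair_differences[("a", "b")] == 0

    def test_single_row_is_error(self):
        with pytest.raises(ValueError):
            alignment_stats(Supermatrix(["a"], ["ACGT"], []))

    def test_difference_counts_match_simulated_truth(self, genome_family):
        genomes, diffs, _ = genome_family
        taxa = sorted(genomes)
        groups = extract_cds_groups([genomes[t] for t in taxa])
        sm = concatenate([align_gene(g, grp) for g, grp in groups.items()], taxa)
        gapfree, _, after = remove_gap_columns(sm)
        for _, row in diffs.iterrows():
            key = (row["taxon_a"], row["taxon_b"])
            assert after.pair_differences[key] == row["n_diff_coding"]


class TestIO:
    def test_nexus_and_fasta_round_trip(self, tmp_path):
        sm = Supermatrix(["a", "b"], ["ATGGCA", "ATGTCA"], [("g", 0, 6)])
        write_supermatrix_nexus(sm, tmp_path / "m.nex")
        text = (tmp_path / "m.nex").read_text()
        assert "NCHAR=6" in text and "CHARSET g = 1-6" in text
        write_supermatrix_fasta(sm, tmp_path / "m.fasta")
        back = read_alignment_fasta(tmp_path / "m.fasta")
        assert back.taxa == sm.taxa and back.rows == sm.rows
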