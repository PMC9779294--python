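import numpy as np
import pytest

from mecp2locus.align import (
    exon_provenance,
    global_align,
    locate_novel_fragment,
    shared_terminal_fragment,
    terminal_diff,
)
from oracles import brute_force_global_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _novel_peptide(panel, iso_id):
    truth = panel.truths[iso_id]
    seq = panel.isoforms[iso_id].sequence
    return "".join(seq[i] for i, (ex, _) in enumerate(truth.labels) if ex is None)


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        aln = global_align("MKVLAW", "MKVLAW")
        assert aln.aligned_ref == aln.aligned_query == "MKVLAW"
        assert all(rp == qp for rp, qp in aln.column_map)

    def test_single_residue(self):
        aln = global_align("A", "A")
        assert (aln.aligned_ref, aln.aligned_query) == ("A", "A")

    def test_degapped_rows_equal_inputs(self):
        aln = global_align("MKVLAWCC", "MKVAW")
        assert aln.ref_sequence == "MKVLAWCC"
        assert aln.query_sequence == "MKVAW"

    def test_rejects_invalid_symbols_and_empty(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            global_align("MKB1", "MK")
        with pytest.raises(ValueError, match="empty"):
            global_align("", "MK")

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_exhaustive_enumeration(self, seed):
        """Affine-gap optimum equals brute force over all monotone alignments."""
        rng = np.random.default_rng(seed)
        for _ in range(8):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
            assert global_align(a, b).score == pytest.approx(brute_force_global_score(a, b))


class TestTerminalDiff:
    def test_established_isoform_pair_has_21_and_9_distinctive_residues(self, panel):
        e1 = panel.isoforms["isoform2_E1_syn"]
        e2 = panel.isoforms["isoform1_E2_syn"]
        assert terminal_diff(e1, e2) == (21, 9, "N")

    def test_symmetry_under_swap(self, panel):
        e1 = panel.isoforms["isoform2_E1_syn"]
        e2 = panel.isoforms["isoform1_E2_syn"]
        a, b, t = terminal_diff(e2, e1)
        assert (b, a, t) == (21, 9, "N")

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("MKVLAW", "MKVLAW", (0, 0, "N")),
            ("XXAB", "YAB", (2, 1, "N")),
            ("ABYY", "ABW", (2, 1, "C")),
        ],
    )
    def test_examples(self, a, b, expected):
        assert terminal_diff(a, b) == expected

    def test_no_common_terminus_is_an_error(self):
        with pytest.raises(ValueError, match="common terminus"):
            terminal_diff("AAA", "WWW")


class TestSharedTerminalFragment:
    def test_nmd_product_pair_shares_14_c_terminal_residues(self, panel):
        h7 = panel.isoforms["H7BY72_syn"]
        pf93 = panel.isoforms["A0A6Q8PF93_syn"]
        assert shared_terminal_fragment(h7, pf93, "C") == 14

    def test_trivial_cases(self):
        assert shared_terminal_fragment("AC", "WY", "C") == 0
        assert shared_terminal_fragment("MKVL", "MKVL", "N") == 4
        with pytest.raises(ValueError, match="terminus"):
            shared_terminal_fragment("A", "A", "Z")


class TestExonProvenance:
    def test_concatenated_exons_have_no_novel_segments(self, panel):
        peps = panel.exon_peptides
        iso = peps[2] + peps[3] + peps[4]
        track = exon_provenance(iso, peps)
        assert track.novel_segments == []
        assert [ex for ex, _ in track.labels[:9]] == [2] * 9

    def test_e1_style_isoform_has_exon1_run_and_no_exon2(self, panel):
        track = exon_provenance(panel.isoforms["isoform2_E1_syn"], panel.exon_peptides)
        exons = {ex for ex, _ in track.labels}
        assert [ex for ex, _ in track.labels[:21]] == [1] * 21
        assert 2 not in exons

    def test_intron_derived_c_terminus_is_one_novel_segment(self, panel):
        iso = panel.isoforms["A0A6Q8PF93_syn"]
        track = exon_provenance(iso, panel.exon_peptides)
        assert track.novel_segments == [(10, len(iso.sequence))]

    def test_provenance_stable_under_fasta_round_trip(self, panel, tmp_path):
        from mecp2locus.io import FastaRecord, write_fasta
        from mecp2locus.locus import read_protein_fasta

        iso = panel.isoforms["B5MCB4_syn"]
        path = tmp_path / "iso.fa"
        write_fasta(path, [FastaRecord(iso.id, iso.sequence)])
        reread = read_protein_fasta(path)[0]
        assert (
            exon_provenance(reread, panel.exon_peptides).labels
            == exon_provenance(iso, panel.exon_peptides).labels
        )


class TestAnnotatedAlignment:
    def test_annotation_row_marks_exons_and_novel_residues(self, panel):
        from mecp2locus.align import format_annotated_alignment

        iso = panel.isoforms["A0A6Q8PF93_syn"]
        aln = global_align(panel.reference, iso)
        track = exon_provenance(iso, panel.exon_peptides)
        text = format_annotated_alignment(aln, track)
        assert "2" in text and "*" in text  # exon-2 run and novel C-terminus
        # every query residue appears annotated exactly once
        marks = "".join(line[12:] for line in text.splitlines() if line.startswith("exon"))
        assert sum(c != " " for c in marks) == len(iso.sequence)


class TestLocateNovelFragment:
    def test_intron2_translation_found_in_intron_2(self, panel):
        origin = locate_novel_fragment(_novel_peptide(panel, "A0A6Q8PF93_syn"), panel.gene, panel.dna)
        assert origin.locus_feature == ("intron", 2)
        assert origin.match_identity == 1.0

    def test_shifted_frame_exon4_translation_found_in_exon_4(self, panel):
        origin = locate_novel_fragment(_novel_peptide(panel, "B5MCB4_syn"), panel.gene, panel.dna)
        assert origin.locus_feature == ("exon", 4)
        assert origin.match_identity == 1.0

    def test_random_peptide_matches_nothing(self, panel):
        rng = np.random.default_rng(11)
        peptide = "".join(rng.choice(list(AA), size=30))
        origin = locate_novel_fragment(peptide, panel.gene, panel.dna, min_identity=0.9)
        assert origin.locus_feature is None
        assert origin.match_identity < 0.9

    def test_short_peptide_rejected(self, panel):
        with pytest.raises(ValueError, match="at least 6"):
            locate_novel_fragment("MKV", panel.gene, panel.dna)
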