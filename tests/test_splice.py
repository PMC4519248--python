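"""Genotyping arithmetic, indel calling and splice-outcome prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fintrace.locus import example_locus
from fintrace.splice import (
    GeneModel,
    Mutation,
    PrimerPair,
    SpliceModelError,
    affects_splice_donor,
    amplicon_length,
    apply_mutation,
    call_indels,
    edited_transcript,
    genomic_to_transcript,
    is_in_frame_skip,
    predict_transcript_outcome,
    skipped_product_length,
    t7ei_cut_position,
    t7ei_fragments,
    to_one_based_inclusive,
    to_zero_based_half_open,
    transcript_sequence,
)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="module")
def fixture():
    return example_locus()


class TestCoordinates:
    def test_round_trip(self):
        assert to_one_based_inclusive(to_zero_based_half_open((13, 54))) == (13, 54)
        assert to_zero_based_half_open((1, 10)) == (0, 10)


class TestGeneModelValidation:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(SpliceModelError):
            GeneModel("g", "A" * 100, ((1, 30), (25, 60)))

    def test_short_intron_rejected(self):
        with pytest.raises(SpliceModelError, match="intron"):
            GeneModel("g", "A" * 100, ((1, 30), (32, 60)))

    def test_exon_outside_sequence_rejected(self):
        with pytest.raises(SpliceModelError):
            GeneModel("g", "A" * 50, ((1, 30), (40, 60)))


class TestAmplicon:
    def test_full_span_primers(self, rng):
        seq = random_seq(rng, 100)
        primers = PrimerPair(seq[:20], revcomp(seq[80:]))
        assert amplicon_length(seq, primers) == 100

    def test_internal_deletion_shortens_by_its_length(self, fixture):
        ref = fixture.model.reference_sequence
        e14 = fixture.model.exons[4]
        mutated = apply_mutation(ref, Mutation("d10", "deletion", e14[0] + 5, 10))
        wt = amplicon_length(ref, fixture.genotyping_primers)
        assert amplicon_length(mutated, fixture.genotyping_primers) == wt - 10

    def test_planted_primers_match_position_arithmetic(self, rng):
        for _ in range(25):
            n = int(rng.integers(120, 400))
            seq = list(random_seq(rng, n))
            i = int(rng.integers(0, n - 90))
            j = int(rng.integers(i + 45, n - 22))
            fwd = random_seq(rng, 20)
            rev = random_seq(rng, 21)
            seq[i : i + 20] = fwd
            seq[j : j + 21] = revcomp(rev)
            template = "".join(seq)
            if template.count(fwd) != 1 or template.count(revcomp(rev)) != 1:
                continue
            assert amplicon_length(template, PrimerPair(fwd, rev)) == j + 21 - i

    def test_absent_primer_rejected(self, rng):
        seq = random_seq(rng, 100)
        with pytest.raises(SpliceModelError, match="not found"):
            amplicon_length(seq, PrimerPair("A" * 25, "C" * 25))

    def test_multiply_mapping_primer_rejected(self):
        seq = "ATGCATGCA" * 10
        with pytest.raises(SpliceModelError, match="maps"):
            amplicon_length(seq, PrimerPair("ATGCATGC", "TTTTTTTT"))


def random_gene_model(rng):
    """A 3-exon model with primers planted in the flanking exons."""
    e_lens = rng.integers(60, 120, size=3)
    i_lens = rng.integers(20, 60, size=2)
    parts, exons, pos = [], [], 1
    for k in range(3):
        exons.append((pos, pos + int(e_lens[k]) - 1))
        parts.append(random_seq(rng, int(e_lens[k])))
        pos += int(e_lens[k])
        if k < 2:
            intron = "GT" + random_seq(rng, int(i_lens[k]) - 4) + "AG"
            parts.append(intron)
            pos += int(i_lens[k])
    model = GeneModel("rand", "".join(parts), tuple(exons))
    tr = transcript_sequence(model)
    fwd = tr[5:25]
    rev = revcomp(tr[-25:-5])
    primers = PrimerPair(fwd, rev)
    skipped = transcript_sequence(model, skip_exon_index=1)
    for probe in (fwd, revcomp(rev)):
        if tr.count(probe) != 1 or skipped.count(probe) != 1:
            return None
    return model, primers


class TestSkippedProduct:
    def test_reported_product_sizes(self):
        assert skipped_product_length(298, 54) == 244

    def test_empty_exon_identity(self):
        assert skipped_product_length(150, 0) == 150

    def test_exon_longer_than_product_rejected(self):
        with pytest.raises(SpliceModelError):
            skipped_product_length(54, 298)

    def test_matches_sequence_level_amplicon_on_random_models(self, rng):
        checked = 0
        while checked < 15:
            built = random_gene_model(rng)
            if built is None:
                continue
            model, primers = built
            wt = amplicon_length(transcript_sequence(model), primers)
            skipped = amplicon_length(transcript_sequence(model, 1), primers)
            assert skipped_product_length(wt, model.exon_length(1)) == skipped
            checked += 1


class TestFrameRule:
    def test_exhaustive_modulo_agreement(self):
        for n in range(301):
            assert is_in_frame_skip(n) == (n % 3 == 0)

    def test_negative_rejected(self):
        with pytest.raises(SpliceModelError):
            is_in_frame_skip(-3)


class TestT7EI:
    def test_reported_fragments(self):
        assert t7ei_fragments(246, 136) == (136, 110)

    def test_equal_halves(self):
        assert t7ei_fragments(200, 100) == (100, 100)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(2, 5000), st.data())
    def test_fragments_always_sum_to_amplicon(self, amplicon, data):
        cut = data.draw(st.integers(1, amplicon - 1))
        f1, f2 = t7ei_fragments(amplicon, cut)
        assert f1 + f2 == amplicon and f1 > 0 and f2 > 0

    def test_cut_outside_amplicon_rejected(self):
        with pytest.raises(SpliceModelError):
            t7ei_fragments(246, 246)

    def test_cut_helper_uses_indel_midpoint(self):
        mut = Mutation("m", "deletion", 100, 4)  # footprint 100..103, mid 101
        assert t7ei_cut_position(mut, 50) == 52


def leftmost_equivalent_deletion(ref, read, length):
    """Independent oracle: smallest 1-based start whose deletion yields read."""
    for pos in range(1, len(ref) - length + 2):
        if ref[: pos - 1] + ref[pos - 1 + length :] == read:
            return pos
    raise AssertionError("no placement found")


class TestCallIndels:
    def test_identical_sequences_no_calls(self, rng):
        seq = random_seq(rng, 200)
        assert call_indels(seq, seq) == []

    def test_planted_deletions_recovered_left_aligned(self, rng):
        for _ in range(100):
            ref = random_seq(rng, int(rng.integers(150, 350)))
            length = int(rng.integers(2, 21))
            pos = int(rng.integers(20, len(ref) - length - 20))
            read = ref[: pos - 1] + ref[pos - 1 + length :]
            calls = call_indels(ref, read, min_indel_bp=2)
            assert len(calls) == 1
            (mut,) = calls
            assert mut.kind == "deletion" and mut.length == length
            assert mut.position == leftmost_equivalent_deletion(ref, read, length)

    def test_planted_insertions_recovered(self, rng):
        for _ in range(25):
            ref = random_seq(rng, 250)
            length = int(rng.integers(2, 15))
            pos = int(rng.integers(20, 230))
            ins = random_seq(rng, length)
            read = ref[:pos] + ins + ref[pos:]
            calls = call_indels(ref, read, min_indel_bp=2)
            assert len(calls) == 1
            (mut,) = calls
            assert mut.kind == "insertion" and mut.length == length
            assert apply_mutation(ref, mut) == read  # placement equivalent

    def test_length_filter_modes(self, rng):
        ref = random_seq(rng, 200)
        pos = 90
        read = ref[: pos - 1] + ref[pos:]  # 1 nt deletion
        assert call_indels(ref, read, min_indel_bp=2) == []
        calls = call_indels(ref, read, min_indel_bp=1)
        assert len(calls) == 1 and calls[0].length == 1

    def test_homopolymer_deletion_left_normalized(self):
        ref = "ACGT" + "A" * 8 + "CGTACGTACGTACGTA"
        read = ref[:8] + ref[11:]  # delete 3 of the As somewhere mid-run
        calls = call_indels(ref, read, min_indel_bp=2)
        assert len(calls) == 1
        assert calls[0].position == 5  # first A of the run
        assert calls[0].length == 3

    def test_empty_input_rejected(self):
        with pytest.raises(SpliceModelError):
            call_indels("", "ACGT")


class TestSpliceDonor:
    def test_deletion_covering_first_two_intron_bases(self, fixture):
        model = fixture.model
        donor_start = model.exons[4][1] + 1
        assert affects_splice_donor(
            Mutation("m", "deletion", donor_start, 2), model, 4
        )

    def test_exonic_deletion_short_of_junction(self, fixture):
        model = fixture.model
        end = model.exons[4][1]
        assert not affects_splice_donor(
            Mutation("m", "deletion", end - 4, 3), model, 4
        )

    def test_insertion_splitting_donor_dinucleotide(self, fixture):
        model = fixture.model
        donor_start = model.exons[4][1] + 1
        assert affects_splice_donor(
            Mutation("m", "insertion", donor_start, 4, "ACGT"), model, 4
        )
        assert not affects_splice_donor(
            Mutation("m", "insertion", donor_start + 1, 4, "ACGT"), model, 4
        )

    def test_mutation_panel_classification(self, fixture):
        flags = [
            affects_splice_donor(m, fixture.model, fixture.target_exon_index)
            for m in fixture.mutations
        ]
        assert flags.count(True) == 5
        assert dict(zip([m.id for m in fixture.mutations], flags))["M4"] is False

    def test_last_exon_has_no_donor(self, fixture):
        with pytest.raises(SpliceModelError, match="donor"):
            affects_splice_donor(
                Mutation("m", "deletion", 5, 2), fixture.model, len(fixture.model.exons) - 1
            )


class TestTranscriptOutcome:
    def test_donor_deletion_upstream_of_in_frame_exon(self, fixture):
        donor_start = fixture.model.exons[4][1] + 1
        out = predict_transcript_outcome(
            Mutation("m", "deletion", donor_start, 4), fixture.model
        )
        assert out.outcome == "exon_skip_in_frame" and out.exon_index == 4
        assert "prediction" in out.caveat

    def test_exonic_single_base_deletion_frameshift(self, fixture):
        e14 = fixture.model.exons[4]
        out = predict_transcript_outcome(
            Mutation("m", "deletion", e14[0] + 10, 1), fixture.model
        )
        assert out.outcome == "coding_frameshift"

    def test_exonic_triplet_deletion_in_frame(self, fixture):
        e14 = fixture.model.exons[4]
        out = predict_transcript_outcome(
            Mutation("m", "deletion", e14[0] + 10, 3), fixture.model
        )
        assert out.outcome == "coding_in_frame_del"

    def test_deep_intronic_deletion_predicted_silent(self, fixture):
        intron13_mid = fixture.model.exons[4][0] - 40
        out = predict_transcript_outcome(
            Mutation("m", "deletion", intron13_mid, 3), fixture.model
        )
        assert out.outcome == "no_effect_predicted"

    def test_skip_of_non_triplet_exon_is_frameshift(self):
        model = GeneModel(
            "g",
            "A" * 40 + "GT" + "T" * 26 + "AG" + "C" * 50 + "GT" + "T" * 30 + "AG" + "G" * 40,
            ((1, 40), (71, 120), (155, 194)),  # middle exon is 50 nt (not 3n)
        )
        donor_start = 121
        out = predict_transcript_outcome(
            Mutation("m", "deletion", donor_start, 2), model
        )
        assert out.outcome == "exon_skip_frameshift"

    def test_mutation_outside_model_rejected(self, fixture):
        n = len(fixture.model.reference_sequence)
        with pytest.raises(SpliceModelError, match="outside"):
            predict_transcript_outcome(
                Mutation("m", "deletion", n + 5, 2), fixture.model
            )


class TestTranscriptMapping:
    def test_exonic_positions_map_contiguously(self, fixture):
        model = fixture.model
        t = 0
        for start, end in model.exons:
            for pos in (start, end):
                expected = sum(
                    e - s + 1 for s, e in model.exons if e < pos
                ) + (pos - start + 1)
                assert genomic_to_transcript(model, pos) == expected
            t += end - start + 1

    def test_intronic_position_rejected(self, fixture):
        with pytest.raises(SpliceModelError, match="exonic"):
            genomic_to_transcript(fixture.model, fixture.model.exons[0][1] + 1)

    def test_edited_transcript_shrinks_by_deletion(self, fixture):
        e14 = fixture.model.exons[4]
        mut = Mutation("m", "deletion", e14[0] + 5, 4)
        wt = transcript_sequence(fixture.model)
        assert len(edited_transcript(fixture.model, mut)) == len(wt) - 4


class TestExampleLocus:
    def test_reported_product_sizes_emerge_from_sequences(self, fixture):
        genomic = fixture.model.reference_sequence
        assert amplicon_length(genomic, fixture.genotyping_primers) == 246
        wt = amplicon_length(transcript_sequence(fixture.model), fixture.transcript_primers)
        skipped = amplicon_length(
            transcript_sequence(fixture.model, fixture.target_exon_index),
            fixture.transcript_primers,
        )
        assert (wt, skipped) == (298, 244)
        assert fixture.model.exon_length(fixture.target_exon_index) == 54

    def test_donor_junction_splits_amplicon_as_reported(self, fixture):
        model = fixture.model
        gp1_start = model.reference_sequence.index(
            fixture.genotyping_primers.forward_sequence
        ) + 1
        junction_offset = model.exons[4][1] - gp1_start + 1
        assert t7ei_fragments(246, junction_offset) == (136, 110)

    def test_intron_boundaries_canonical(self, fixture):
        ref = fixture.model.reference_sequence
        for k in range(len(fixture.model.exons) - 1):
            end = fixture.model.exons[k][1]
            nxt = fixture.model.exons[k + 1][0]
            assert ref[end : end + 2] == "GT"
            assert ref[nxt - 3 : nxt - 1] == "AG"
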