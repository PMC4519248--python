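"""Genotyping and transcript arithmetic for splice-donor mutagenesis.

Covers the sequence-level bookkeeping of a TALEN/CRISPR splice-donor
mutagenesis screen: PCR amplicon sizes, T7 endonuclease I cleavage
fragments, indel calling from Sanger reads with the mosaic-screen length
filter, classification of indels against the splice donor (the first two
nucleotides of the downstream intron), and prediction of the transcript
outcome (in-frame exon skip, frameshifting skip, or coding indel).

Coordinates are 1-based inclusive, the way loci are annotated; helpers
convert to 0-based half-open.  Splicing outcomes are sequence-based
predictions only — surveillance pathways such as nonsense-mediated decay
can remove the predicted transcript entirely, so every prediction
carries an explicit caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

OUTCOMES = (
    "no_effect_predicted",
    "exon_skip_in_frame",
    "exon_skip_frameshift",
    "coding_frameshift",
    "coding_in_frame_del",
)

SPLICE_CAVEAT = (
    "sequence-based prediction: splice-site disruption is inferred from the "
    "first-two-intron-nucleotide rule; transcript surveillance (e.g. NMD) can "
    "degrade the predicted product so RT-PCR confirmation is required"
)


class SpliceModelError(ValueError):
    pass


def to_zero_based_half_open(interval: tuple[int, int]) -> tuple[int, int]:
    """(start, end) 1-based inclusive -> 0-based half-open."""
    start, end = interval
    return start - 1, end


def to_one_based_inclusive(interval: tuple[int, int]) -> tuple[int, int]:
    """(start, end) 0-based half-open -> 1-based inclusive."""
    start, end = interval
    return start + 1, end


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure on a reference sequence.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals in
    transcription order on the plus strand of ``reference_sequence``.
    """

    name: str
    reference_sequence: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_sequence", self.reference_sequence.upper())
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        if self.strand not in "+-":
            raise SpliceModelError("strand must be '+' or '-'")
        n = len(self.reference_sequence)
        prev_end = 0
        for start, end in self.exons:
            if not 1 <= start <= end <= n:
                raise SpliceModelError(f"exon ({start},{end}) outside sequence of length {n}")
            if start <= prev_end:
                raise SpliceModelError("exons must be ordered and non-overlapping")
            if prev_end and start - prev_end - 1 < 2:
                raise SpliceModelError("each intron must be at least 2 nt")
            prev_end = end

    def exon_length(self, exon_index: int) -> int:
        start, end = self.exons[exon_index]
        return end - start + 1

    def donor_window(self, exon_index: int, width: int = 2) -> tuple[int, int]:
        """1-based interval of the first ``width`` nt of the downstream intron."""
        if exon_index < 0 or exon_index >= len(self.exons):
            raise SpliceModelError(f"no exon with index {exon_index}")
        if exon_index == len(self.exons) - 1:
            raise SpliceModelError("last exon has no splice donor")
        end = self.exons[exon_index][1]
        return end + 1, end + width


@dataclass(frozen=True)
class Mutation:
    """A single indel on the reference.

    Deletions remove ``length`` bases starting at 1-based ``position``;
    insertions place ``inserted_sequence`` immediately after ``position``
    (``position = 0`` inserts before the first base).
    """

    id: str
    kind: str  # "deletion" | "insertion"
    position: int
    length: int
    inserted_sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise SpliceModelError(f"unknown mutation kind {self.kind!r}")
        if self.length <= 0:
            raise SpliceModelError("mutation length must be positive")
        if self.kind == "insertion" and len(self.inserted_sequence) != self.length:
            raise SpliceModelError("inserted_sequence length must equal length")

    def footprint(self) -> tuple[int, int]:
        """1-based closed interval of reference bases touched.

        For an insertion the footprint is the two flanking bases, since
        the event sits between them.
        """
        if self.kind == "deletion":
            return self.position, self.position + self.length - 1
        return self.position, self.position + 1

    @property
    def net_length_change(self) -> int:
        return self.length if self.kind == "insertion" else -self.length


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers (both written 5'->3')."""

    forward_sequence: str
    reverse_sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward_sequence", self.forward_sequence.upper())
        object.__setattr__(self, "reverse_sequence", self.reverse_sequence.upper())
        if not self.forward_sequence or not self.reverse_sequence:
            raise SpliceModelError("primers must be non-empty")


def apply_mutation(reference: str, mut: Mutation) -> str:
    """Return the mutated sequence."""
    n = len(reference)
    if mut.kind == "deletion":
        if not 1 <= mut.position or mut.position + mut.length - 1 > n:
            raise SpliceModelError(f"deletion {mut.id} outside reference of length {n}")
        return reference[: mut.position - 1] + reference[mut.position - 1 + mut.length :]
    if not 0 <= mut.position <= n:
        raise SpliceModelError(f"insertion {mut.id} outside reference of length {n}")
    return reference[: mut.position] + mut.inserted_sequence + reference[mut.position :]


def transcript_sequence(model: GeneModel, skip_exon_index: int | None = None) -> str:
    """Spliced mRNA sequence, optionally with one exon skipped."""
    parts = []
    for i, (start, end) in enumerate(model.exons):
        if i == skip_exon_index:
            continue
        parts.append(model.reference_sequence[start - 1 : end])
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def amplicon_length(seq: str, primers: PrimerPair) -> int:
    """PCR product length: forward 5' start through reverse 5' start.

    Both primers (the reverse one as its reverse complement) must occur
    exactly once in ``seq``.
    """
    seq = seq.upper()
    fwd = primers.forward_sequence
    rev_rc = str(Seq(primers.reverse_sequence).reverse_complement())
    for name, probe in (("forward", fwd), ("reverse", rev_rc)):
        hits = seq.count(probe)
        if hits == 0:
            raise SpliceModelError(f"{name} primer not found in template")
        if hits > 1:
            raise SpliceModelError(f"{name} primer maps {hits} times in template")
    i = seq.index(fwd)
    j = seq.index(rev_rc)
    length = j + len(rev_rc) - i
    if j < i or length < len(fwd) + len(rev_rc):
        raise SpliceModelError("reverse primer binds upstream of (or overlapping) the forward primer")
    return length


def skipped_product_length(wt_product_bp: int, exon_length_bp: int) -> int:
    """RT-PCR product size after skipping an exon of the given length."""
    if exon_length_bp < 0:
        raise SpliceModelError("exon length must be non-negative")
    if exon_length_bp >= wt_product_bp:
        raise SpliceModelError("skipped exon must be shorter than the wild-type product")
    return wt_product_bp - exon_length_bp


def is_in_frame_skip(exon_length_bp: int) -> bool:
    """True when removing the exon preserves the downstream reading frame."""
    if exon_length_bp < 0:
        raise SpliceModelError("exon length must be non-negative")
    return exon_length_bp % 3 == 0


def t7ei_fragments(amplicon_bp: int, cut_position_bp: int) -> tuple[int, int]:
    """Sizes of the two cleavage fragments of a heteroduplex amplicon."""
    if not 0 < cut_position_bp < amplicon_bp:
        raise SpliceModelError("cut position must be strictly inside the amplicon")
    return cut_position_bp, amplicon_bp - cut_position_bp


def t7ei_cut_position(mut: Mutation, amplicon_start: int) -> int:
    """Approximate cleavage offset: the indel midpoint on the heteroduplex.

    ``amplicon_start`` is the 1-based reference position of the forward
    primer's 5' end.  T7EI cuts near the mismatch bubble; the midpoint of
    the indel footprint is a serviceable approximation.
    """
    start, end = mut.footprint()
    mid = (start + end) // 2
    cut = mid - amplicon_start + 1
    if cut <= 0:
        raise SpliceModelError("mutation lies outside the amplicon")
    return cut


# ---------------------------------------------------------------------------
# indel calling
# ---------------------------------------------------------------------------

_MERGE_MAX_SPACER_NT = 2  # gap runs separated by < 3 aligned nt are one event


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _left_align_deletion(reference: str, pos_1b: int, length: int) -> int:
    s = pos_1b - 1
    while s > 0 and reference[s - 1] == reference[s + length - 1]:
        s -= 1
    return s + 1


def _left_align_insertion(reference: str, pos_1b: int, inserted: str) -> tuple[int, str]:
    pos, seq = pos_1b, inserted
    while pos >= 1 and seq and seq[-1] == reference[pos - 1]:
        seq = reference[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def call_indels(reference: str, read: str, min_indel_bp: int = 2) -> list[Mutation]:
    """Call left-aligned indels from a read against a reference.

    A global alignment with affine gap penalties is computed; each
    contiguous gap run becomes a candidate event.  Opposite-kind runs
    separated by fewer than 3 aligned nucleotides are merged into one
    event of the net length change (a heuristic for aligner-split
    breakpoints; balanced del+ins blocks are kept separate).  Events
    shorter than ``min_indel_bp`` are discarded — use 2 for F0 mosaic
    screening (suppresses polymerase slippage artifacts) and 1 when
    confirming a known allele in F1 carriers.
    """
    if not reference or not read:
        raise SpliceModelError("reference and read must be non-empty")
    if min_indel_bp < 1:
        raise SpliceModelError("min_indel_bp must be >= 1")
    reference = reference.upper()
    read = read.upper()
    if read == reference:
        return []
    alignment = _aligner().align(reference, read)[0]
    ref_blocks, read_blocks = alignment.aligned
    # walk the gaps between aligned blocks (plus leading/trailing gaps)
    events: list[tuple[str, int, int, str]] = []  # (kind, ref_pos_0b, length, inserted)
    prev_r, prev_q = 0, 0
    boundaries = list(zip(ref_blocks, read_blocks)) + [
        ((len(reference), len(reference)), (len(read), len(read)))
    ]
    for (r0, r1), (q0, q1) in boundaries:
        if r0 > prev_r:
            events.append(("deletion", prev_r, r0 - prev_r, ""))
        if q0 > prev_q:
            events.append(("insertion", prev_r, q0 - prev_q, read[prev_q:q0]))
        prev_r, prev_q = r1, q1
    events = _merge_adjacent(events, reference)
    out: list[Mutation] = []
    for k, (kind, ref_pos, length, inserted) in enumerate(events):
        if length < min_indel_bp:
            continue
        if kind == "deletion":
            pos = _left_align_deletion(reference, ref_pos + 1, length)
            out.append(Mutation(f"indel_{k}", "deletion", pos, length))
        else:
            pos, seq = _left_align_insertion(reference, ref_pos, inserted)
            out.append(Mutation(f"indel_{k}", "insertion", pos, length, seq))
    return out


def _merge_adjacent(events, reference):
    """Merge gap runs separated by < 3 aligned nt into net-length events."""
    merged = []
    i = 0
    while i < len(events):
        kind, pos, length, inserted = events[i]
        net = length if kind == "insertion" else -length
        j = i + 1
        leftmost = pos
        while j < len(events):
            nkind, npos, nlength, nins = events[j]
            prev_end = events[j - 1][1] + (events[j - 1][2] if events[j - 1][0] == "deletion" else 0)
            spacer = npos - prev_end
            if spacer > _MERGE_MAX_SPACER_NT:
                break
            cand = net + (nlength if nkind == "insertion" else -nlength)
            if cand == 0 and j == i + 1 and kind != nkind:
                break  # balanced substitution block, keep events separate
            net = cand
            inserted = inserted + nins
            j += 1
        if j == i + 1:
            merged.append(events[i])
        elif net < 0:
            merged.append(("deletion", leftmost, -net, ""))
        elif net > 0:
            merged.append(("insertion", leftmost, net, inserted[:net]))
        i = j
    return merged


def genomic_to_transcript(model: GeneModel, pos: int) -> int:
    """Map a 1-based genomic position inside an exon to the transcript.

    Plus-strand models only; raises for intronic positions.
    """
    if model.strand != "+":
        raise SpliceModelError("transcript mapping implemented for plus-strand models")
    offset = 0
    for start, end in model.exons:
        if start <= pos <= end:
            return offset + (pos - start) + 1
        offset += end - start + 1
    raise SpliceModelError(f"position {pos} is not exonic")


def edited_transcript(model: GeneModel, mut: Mutation) -> str:
    """Spliced transcript carrying a purely exonic indel."""
    if mut.kind == "deletion":
        f_start, f_end = mut.footprint()
        t_start = genomic_to_transcript(model, f_start)
        t_end = genomic_to_transcript(model, f_end)
        if t_end - t_start != f_end - f_start:
            raise SpliceModelError(f"mutation {mut.id} is not contained in a single exon")
        tmut = Mutation(mut.id, "deletion", t_start, mut.length)
    else:
        tmut = Mutation(
            mut.id, "insertion", genomic_to_transcript(model, mut.position),
            mut.length, mut.inserted_sequence,
        )
    return apply_mutation(transcript_sequence(model), tmut)


def affects_splice_donor(
    mut: Mutation, model: GeneModel, exon_index: int, donor_width: int = 2
) -> bool:
    """Does the mutation hit the first ``donor_width`` nt of the intron
    following ``exon_index`` (0-based)?

    Deletions disrupt when their footprint overlaps the window; an
    insertion disrupts when its insertion point falls at the exon/intron
    junction or inside the window (it separates or splits the donor
    dinucleotide).
    """
    w_start, w_end = model.donor_window(exon_index, donor_width)
    if mut.kind == "deletion":
        f_start, f_end = mut.footprint()
        return f_start <= w_end and f_end >= w_start
    return w_start - 1 <= mut.position <= w_end - 1


@dataclass(frozen=True)
class TranscriptOutcome:
    mutation_id: str
    outcome: str  # member of OUTCOMES
    exon_index: int | None  # exon skipped or hit, when applicable
    caveat: str = SPLICE_CAVEAT


def predict_transcript_outcome(
    mut: Mutation, model: GeneModel, donor_width: int = 2
) -> TranscriptOutcome:
    """Rule cascade from indel footprint to predicted transcript effect.

    Donor-disrupting events skip the preceding exon (frame decided by the
    exon length mod 3); purely exonic indels shift or preserve the coding
    frame by their net length; anything else is predicted silent.  The
    result always carries the prediction caveat.
    """
    n = len(model.reference_sequence)
    f_start, f_end = mut.footprint()
    if f_start < 1 or f_end > n:
        raise SpliceModelError(f"mutation {mut.id} outside the modeled region")
    for i in range(len(model.exons) - 1):
        if affects_splice_donor(mut, model, i, donor_width):
            in_frame = is_in_frame_skip(model.exon_length(i))
            return TranscriptOutcome(
                mut.id,
                "exon_skip_in_frame" if in_frame else "exon_skip_frameshift",
                i,
            )
    for i, (start, end) in enumerate(model.exons):
        overlaps = (
            f_start <= end and f_end >= start
            if mut.kind == "deletion"
            else start <= mut.position < end  # insertion strictly inside the exon
        )
        if overlaps:
            if abs(mut.net_length_change) % 3 == 0:
                return TranscriptOutcome(mut.id, "coding_in_frame_del", i)
            return TranscriptOutcome(mut.id, "coding_frameshift", i)
    return TranscriptOutcome(mut.id, "no_effect_predicted", None)


def mutation_report(
    model: GeneModel,
    mutations,
    rt_primers: PrimerPair,
    donor_width: int = 2,
) -> list[dict]:
    """Per-mutation genotyping summary rows.

    Columns: mutation id, whether any splice donor is hit, the predicted
    transcript outcome, and the wild-type vs predicted mutant RT-PCR
    product sizes (the mutant product is measured on the predicted
    transcript sequence: exon-skipped for donor hits, indel-edited for
    exonic events, unchanged otherwise).
    """
    wt_transcript = transcript_sequence(model)
    wt_product = amplicon_length(wt_transcript, rt_primers)
    rows = []
    for mut in mutations:
        pred = predict_transcript_outcome(mut, model, donor_width)
        if pred.outcome.startswith("exon_skip"):
            mut_seq = transcript_sequence(model, skip_exon_index=pred.exon_index)
        elif pred.outcome.startswith("coding"):
            mut_seq = edited_transcript(model, mut)
        else:
            mut_seq = wt_transcript
        rows.append(
            {
                "id": mut.id,
                "affects_donor": pred.outcome.startswith("exon_skip"),
                "outcome": pred.outcome,
                "wt_product_bp": wt_product,
                "mut_product_bp": amplicon_length(mut_seq, rt_primers),
            }
        )
    return rows
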