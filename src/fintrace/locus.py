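"""Synthetic splice-mutagenesis locus fixture.

Builds a fully synthetic gene model shaped like the zebrafish *col6a1*
exon 10–16 region used for splice-donor mutagenesis: seven exons, a
54 bp in-frame target exon (the fifth, "exon 14"), genotyping primers
flanking that exon giving a 246 bp amplicon whose donor junction sits
136 bp from the forward primer (hence 136 + 110 bp T7EI fragments), and
transcript primers in the first and last exons giving a 298 bp spliced
product (244 bp when the target exon is skipped).  The filler sequence
is random (fixed seed); only the printed primer sequences, segment
lengths and GT/AG intron boundaries are meaningful.

Also builds a panel of six example indels mirroring the footprint
classes reported for such screens: five deletions overlapping the splice
donor and one 1 nt exonic deletion (a frameshift allele that survives an
F0 screen only when the indel-length filter is relaxed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .splice import GeneModel, Mutation, PrimerPair

GENOTYPING_PRIMERS = PrimerPair("TGCCACCATGAAGAAGAGTG", "TCAGATGTGAGTTGCTCAGAC")
TRANSCRIPT_PRIMERS = PrimerPair("GGTCCAGTCGGTTACCAAGG", "CAGATGGTCCGTAGTTTCCAGG")

#: 0-based index of the 54 bp target exon within the model's exon list
TARGET_EXON_INDEX = 4

_SEED = 20150721

# segment lengths: lead, e10, i10, e11, i11, e12, i12, e13, i13, e14,
# i14, e15, i15, e16, tail
_SEGMENTS = (30, 60, 40, 30, 40, 30, 40, 40, 120, 54, 140, 40, 40, 100, 30)
_EXON_SEGMENT_IDX = (1, 3, 5, 7, 9, 11, 13)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LocusFixture:
    model: GeneModel
    genotyping_primers: PrimerPair
    transcript_primers: PrimerPair
    mutations: tuple[Mutation, ...]
    target_exon_index: int = TARGET_EXON_INDEX


def example_locus(seed: int = _SEED) -> LocusFixture:
    """Construct the synthetic locus and its mutation panel."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=sum(_SEGMENTS)))

    bounds = np.concatenate([[0], np.cumsum(_SEGMENTS)])
    exons = tuple(
        (int(bounds[i]) + 1, int(bounds[i + 1])) for i in _EXON_SEGMENT_IDX
    )

    def plant(probe: str, start_0b: int) -> None:
        seq[start_0b : start_0b + len(probe)] = list(probe)

    # canonical GT...AG intron boundaries
    for k, (start, end) in enumerate(exons[:-1]):
        intron_start = end  # 0-based index of intron base +1
        intron_end = exons[k + 1][0] - 1  # 0-based, one past intron
        plant("GT", intron_start)
        plant("AG", intron_end - 2)

    e10, e14, e16 = exons[0], exons[TARGET_EXON_INDEX], exons[-1]
    # transcript primers: forward 20 nt into the first exon (40 nt tail),
    # reverse-complement ending 64 nt into the last exon
    plant(TRANSCRIPT_PRIMERS.forward_sequence, e10[0] - 1 + 20)
    sp2_rc = _revcomp(TRANSCRIPT_PRIMERS.reverse_sequence)
    plant(sp2_rc, e16[0] - 1 + 64 - len(sp2_rc))
    # genotyping primers: forward 82 nt upstream of the target exon,
    # reverse-complement ending 110 nt downstream of it
    plant(GENOTYPING_PRIMERS.forward_sequence, e14[0] - 1 - 82)
    gp2_rc = _revcomp(GENOTYPING_PRIMERS.reverse_sequence)
    plant(gp2_rc, e14[1] + 110 - len(gp2_rc))

    reference = "".join(seq)
    model = GeneModel("synthetic_col6a1_like_e10_e16", reference, exons)

    d = e14[1]  # last exonic base before the donor
    mutations = (
        Mutation("M1", "deletion", d - 3, 7),  # spans junction into intron +3
        Mutation("M2", "deletion", d - 4, 10),  # spans junction into intron +5
        Mutation("M3", "deletion", d - 1, 4),  # exon last 2 nt + donor GT
        Mutation("M4", "deletion", d - 10, 1),  # exonic 1 nt frameshift
        Mutation("M5", "deletion", d + 1, 6),  # intronic, starts at donor G
        Mutation("M6", "deletion", d, 9),  # exon last nt + intron first 8
    )

    _check_primer_uniqueness(model)
    return LocusFixture(model, GENOTYPING_PRIMERS, TRANSCRIPT_PRIMERS, mutations)


def _check_primer_uniqueness(model: GeneModel) -> None:
    from .splice import SpliceModelError, transcript_sequence

    genomic = model.reference_sequence
    transcript = transcript_sequence(model)
    probes = {
        "gp forward": (GENOTYPING_PRIMERS.forward_sequence, genomic),
        "gp reverse": (_revcomp(GENOTYPING_PRIMERS.reverse_sequence), genomic),
        "sp forward": (TRANSCRIPT_PRIMERS.forward_sequence, transcript),
        "sp reverse": (_revcomp(TRANSCRIPT_PRIMERS.reverse_sequence), transcript),
    }
    for name, (probe, template) in probes.items():
        if template.count(probe) != 1:
            raise SpliceModelError(f"fixture build failed: {name} primer not unique")
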