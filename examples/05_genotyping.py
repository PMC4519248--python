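"""Splice-mutation genotyping arithmetic on the synthetic locus.

Builds the synthetic seven-exon locus with its 54 bp target exon,
derives every genotyping size from the sequences (nothing is hard-coded)
and classifies the example mutation panel: which indels hit the splice
donor (first two intron nucleotides) and what transcript each predicts.
"""

from fintrace.locus import example_locus
from fintrace.splice import (
    amplicon_length,
    call_indels,
    apply_mutation,
    mutation_report,
    t7ei_fragments,
    transcript_sequence,
)

locus = example_locus()
model = locus.model
genomic = model.reference_sequence

amplicon = amplicon_length(genomic, locus.genotyping_primers)
gp1_start = genomic.index(locus.genotyping_primers.forward_sequence) + 1
junction = model.exons[locus.target_exon_index][1] - gp1_start + 1
f1, f2 = t7ei_fragments(amplicon, junction)
wt = amplicon_length(transcript_sequence(model), locus.transcript_primers)
skipped = amplicon_length(
    transcript_sequence(model, locus.target_exon_index), locus.transcript_primers
)
print(f"genotyping amplicon {amplicon} bp; T7EI fragments {f1} + {f2} bp")
print(f"RT-PCR products: wild type {wt} bp, exon-skipped {skipped} bp "
      f"(exon of {wt - skipped} bp, in frame: {(wt - skipped) % 3 == 0})")

print("\nmutation panel:")
for row in mutation_report(model, locus.mutations, locus.transcript_primers):
    print(f"  {row['id']}: donor hit={row['affects_donor']!s:5}  "
          f"{row['outcome']:20} product {row['mut_product_bp']} bp")

# indel calling demo: sequence a mutant amplicon against the reference
mut = locus.mutations[2]  # the 4 nt donor deletion
read = apply_mutation(genomic, mut)
(call,) = call_indels(genomic, read, min_indel_bp=2)
print(f"\ncalled from mutant read: {call.length} nt {call.kind} at "
      f"position {call.position} (left-aligned)")
# Five of six panel mutations disrupt the donor and predict the 244 bp
# skipped product; the 1 nt exonic deletion predicts a coding frameshift.
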