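"""Consequence arithmetic for alternative splice-donor usage.

A variant that weakens a canonical donor site can shift splicing to
cryptic donors upstream.  Given the observed shift offsets (16 and 129
exonic nucleotides) and the 250 bp RT-PCR product of the canonical
transcript, the module derives each isoform's amplicon size and whether
the transcript stays in frame.
"""

from irdscape import DonorShiftEvent, frame_consequence, isoform_amplicon_size

CANONICAL_BP = 250

for shift in (16, 129):
    event = DonorShiftEvent(shift_nt=shift, canonical_amplicon_bp=CANONICAL_BP)
    size = isoform_amplicon_size(event)
    cons = frame_consequence(event)
    effect = (
        "frameshift (nonproductive transcript)"
        if cons.frameshift
        else f"in-frame deletion of {cons.codons_deleted} codons"
    )
    print(f"donor shift {shift:>3} nt -> {size} bp amplicon, {effect}")

# The 16 nt shift breaks the reading frame, so its transcript is degraded
# or truncated; the 129 nt shift (a multiple of 3) removes 43 residues
# but preserves the frame downstream.
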