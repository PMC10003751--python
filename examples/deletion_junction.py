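"""Deletion length and junction-PCR arithmetic for a two-exon deletion.

A recurrent deletion removes exons 13 and 14 of a large retinal-disease
gene.  From its 1-based inclusive genomic coordinates we compute the
deleted length; from primers flanking the breakpoints we predict the
carrier-specific junction product that a diagnostic PCR amplifies.
"""

from irdscape import deletion_length, junction_product_size

DEL_START, DEL_END = 65_665_873, 65_773_340

bp, kb = deletion_length(DEL_START, DEL_END)
print(f"deletion {DEL_START:,}-{DEL_END:,}: {bp:,} bp = {kb} kb")

# primers placed so the undeleted template spans 107,720 bp: far too long
# to amplify from an intact allele, but collapsing to a short product when
# the deletion fuses the flanks
left_primer_start = DEL_START - 127
right_primer_end = left_primer_start + 107_720 - 1
product = junction_product_size(left_primer_start, right_primer_end, (DEL_START, DEL_END))
print(f"junction PCR product in deletion carriers: {product} bp")
print(f"product from an intact allele: {junction_product_size(left_primer_start, right_primer_end, None):,} bp (no amplification in practice)")
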