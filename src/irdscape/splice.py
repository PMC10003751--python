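"""Consequence arithmetic for alternative splice-donor usage.

When a variant weakens a canonical donor site, splicing can shift to a
cryptic donor a fixed number of exonic nucleotides upstream.  The
transcript then loses exactly that many nucleotides, which determines both
the reading-frame consequence (frameshift unless the shift is a multiple
of three) and the size of the RT-PCR amplicon relative to the canonical
product.  The module consumes observed shift offsets; it does not predict
donor strength.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "DonorShiftEvent",
    "FrameConsequence",
    "frame_consequence",
    "isoform_amplicon_size",
    "premature_stop_codon",
]


@dataclass(frozen=True)
class DonorShiftEvent:
    """An alternative-donor event observed in a transcript assay.

    Parameters
    ----------
    shift_nt
        Distance of the alternative donor upstream of the canonical one,
        in exonic nucleotides (> 0).
    canonical_amplicon_bp
        Size of the RT-PCR product from the canonical transcript.
    cds_offset_of_junction
        Position of the canonical exon junction within the codon frame
        (0–2); needed only for stop-codon localization.
    """

    shift_nt: int
    canonical_amplicon_bp: int
    cds_offset_of_junction: int = 0

    def __post_init__(self) -> None:
        if self.shift_nt <= 0:
            raise ValueError("shift_nt must be positive")
        if not self.shift_nt < self.canonical_amplicon_bp:
            raise ValueError("shift_nt must be smaller than the canonical amplicon")
        if not 0 <= self.cds_offset_of_junction <= 2:
            raise ValueError("cds_offset_of_junction must be in 0..2")


@dataclass(frozen=True)
class FrameConsequence:
    frameshift: bool
    codons_deleted: int | None = None


def frame_consequence(event: DonorShiftEvent) -> FrameConsequence:
    """Reading-frame consequence of a donor shift.

    A shift that is a multiple of 3 deletes ``shift_nt / 3`` codons in
    frame; any other shift disrupts the reading frame.
    """
    if event.shift_nt % 3 != 0:
        return FrameConsequence(frameshift=True)
    return FrameConsequence(frameshift=False, codons_deleted=event.shift_nt // 3)


def isoform_amplicon_size(event: DonorShiftEvent) -> int:
    """RT-PCR product size of the shifted isoform.

    The isoform lacks exactly ``shift_nt`` nucleotides relative to the
    canonical transcript, so ``size = canonical − shift``.
    """
    size = event.canonical_amplicon_bp - event.shift_nt
    if size <= 0:
        raise ValueError("amplicon size must be positive")
    return size


def premature_stop_codon(event: DonorShiftEvent, cds: str | None = None) -> int | str:
    """1-based codon index of the first premature stop in a frameshifted isoform.

    Localizing the stop requires the transcript's coding sequence; without
    it the function reports ``"requires transcript"``.  ``cds`` is the CDS
    of the *shifted* isoform from the start codon onward.
    """
    cons = frame_consequence(event)
    if not cons.frameshift:
        raise ValueError("in-frame events do not create a frameshift stop")
    if cds is None:
        return "requires transcript"
    protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    idx = protein.find("*")
    if idx < 0:
        raise ValueError("no stop codon found in supplied CDS")
    return idx + 1
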