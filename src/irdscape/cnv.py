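"""Exon-resolution CNV calling from sequencing-depth ratios.

Depth per exon is first library-size normalized (each sample scaled so
its total depth matches the cohort median), then converted to a ratio
against the leave-one-out median of the remaining samples at the same
exon.  A diploid exon sits near ratio 1; a heterozygous deletion near
0.5; a homozygous deletion near 0; a single-copy gain near 1.5.  Calls
are maximal runs of consecutive exons of a gene in the same copy-state
band, with a minimum size of one exon and no maximum.

Breakpoint refinement locates the coverage transition in per-base depth
and reports an uncertainty interval constrained to the flanking introns.
Deletion and junction-PCR arithmetic operate on 1-based inclusive
genomic coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .model import CnvCall, CopyState, CoverageMatrix

__all__ = [
    "CnvParams",
    "normalize_depth",
    "call_cnv",
    "deletion_length",
    "refine_breakpoints",
    "junction_product_size",
]


@dataclass(frozen=True)
class CnvParams:
    hom_del_ratio_max: float = 0.15
    het_del_band: tuple[float, float] = (0.35, 0.65)
    dup_ratio_min: float = 1.35
    min_exons: int = 1
    min_reference_samples: int = 8

    def __post_init__(self) -> None:
        lo, hi = self.het_del_band
        if not (self.hom_del_ratio_max < lo < hi < self.dup_ratio_min):
            raise ValueError("copy-state bands must be ordered and non-overlapping")
        if self.min_exons < 1:
            raise ValueError("min_exons must be >= 1")


def normalize_depth(
    matrix: CoverageMatrix,
    params: CnvParams = CnvParams(),
) -> np.ndarray:
    """Leave-one-out depth ratios, shape (n_exons, n_samples).

    Per-sample library size is equalized first, so a sample sequenced at
    half depth genome-wide still shows ratios near 1.  Exons with zero
    depth across the whole cohort are masked to NaN with a warning.
    """
    n_exons, n_samples = matrix.depth.shape
    if n_samples < params.min_reference_samples:
        raise ValueError(
            f"need >= {params.min_reference_samples} samples for a reference set, "
            f"got {n_samples}"
        )
    depth = matrix.depth.astype(float)
    libsize = depth.sum(axis=0)
    if np.any(libsize == 0):
        raise ValueError("sample with zero total depth")
    scaled = depth * (np.median(libsize) / libsize)

    dead = scaled.sum(axis=1) == 0
    if dead.any():
        warnings.warn(
            f"masking {int(dead.sum())} exon(s) with zero depth across the cohort",
            stacklevel=2,
        )

    ratios = np.full_like(scaled, np.nan)
    for j in range(n_samples):
        others = np.delete(scaled, j, axis=1)
        ref = np.median(others, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[:, j] = np.where(ref > 0, scaled[:, j] / ref, np.nan)
    ratios[dead, :] = np.nan
    return ratios


def _state_of(ratio: float, params: CnvParams) -> CopyState | None:
    if np.isnan(ratio):
        return None
    if ratio <= params.hom_del_ratio_max:
        return CopyState.HOM_DEL
    lo, hi = params.het_del_band
    if lo <= ratio <= hi:
        return CopyState.HET_DEL
    if ratio >= params.dup_ratio_min:
        return CopyState.DUP
    return None


def call_cnv(
    matrix: CoverageMatrix,
    ratios: np.ndarray,
    params: CnvParams = CnvParams(),
) -> list[CnvCall]:
    """Maximal runs of consecutive same-state exons, per gene and sample.

    Default breakpoint uncertainty intervals span from the end of the last
    normal exon (exclusive) to the start of the first affected exon, and
    symmetrically on the right — i.e. the flanking introns, or a 1 bp
    interval just outside the terminal exon at gene ends.
    """
    calls: list[CnvCall] = []
    exons = matrix.exons
    for j, sample in enumerate(matrix.samples):
        i = 0
        while i < len(exons):
            state = _state_of(ratios[i, j], params)
            if state is None:
                i += 1
                continue
            gene = exons[i][0]
            k = i
            while (
                k + 1 < len(exons)
                and exons[k + 1][0] == gene
                and _state_of(ratios[k + 1, j], params) is state
            ):
                k += 1
            if k - i + 1 >= params.min_exons:
                left_outer = exons[i - 1][4] + 1 if i > 0 and exons[i - 1][0] == gene else exons[i][3] - 1
                right_outer = (
                    exons[k + 1][3] - 1
                    if k + 1 < len(exons) and exons[k + 1][0] == gene
                    else exons[k][4] + 1
                )
                calls.append(
                    CnvCall(
                        patient_id=sample,
                        gene=gene,
                        first_exon=exons[i][1],
                        last_exon=exons[k][1],
                        copy_state=state,
                        breakpoint_left=(left_outer, exons[i][3]),
                        breakpoint_right=(exons[k][4], right_outer),
                    )
                )
            i = k + 1
    return calls


def deletion_length(g_start: int, g_end: int) -> tuple[int, float]:
    """Length of a deletion from 1-based inclusive genomic coordinates.

    Returns ``(bp, kb)`` with kb rounded half-up to one decimal, e.g.
    ``(65665873, 65773340) -> (107468, 107.5)``.
    """
    if g_start > g_end:
        raise ValueError("inverted interval")
    bp = g_end - g_start + 1
    kb = float(Decimal(bp) / 1000)
    kb = float(Decimal(str(kb)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return bp, kb


# per-copy-state (flank_like_min_or_max, event_like_threshold) fractions of
# the flanking median depth; deletions transition downward, gains upward
_FLANK_EVENT_FRACTIONS = {
    CopyState.HOM_DEL: (0.50, 0.15),
    CopyState.HET_DEL: (0.75, 0.60),
    CopyState.DUP: (1.175, 1.35),
}


def refine_breakpoints(
    positions: np.ndarray,
    depth: np.ndarray,
    call: CnvCall,
    region: tuple[int, int],
    intron_bounds: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Breakpoint uncertainty intervals from a per-base depth track.

    ``region`` is the (start, end) of the called event in genomic
    coordinates.  For a homozygous deletion, bases at >= 50% of the
    flanking median are flank-like and bases below 15% are event-like;
    the left interval runs from just after the last flank-like base to
    the first event-like base, and symmetrically on the right (a clean
    step function yields width-1 intervals).  Heterozygous deletions and
    duplications use analogous thresholds around their expected copy
    ratios.  When no transition is found, the whole flanking intron (or
    the supplied ``intron_bounds``) is returned as the uncertainty;
    otherwise intervals are clipped to ``intron_bounds`` when given.
    """
    positions = np.asarray(positions)
    depth = np.asarray(depth, dtype=float)
    start, end = region
    flank_sel = (positions < start) | (positions > end)
    if not flank_sel.any():
        raise ValueError("no flanking bases available around the called region")
    med = float(np.median(depth[flank_sel]))
    if med <= 0:
        raise ValueError("flanking median depth is zero")

    flank_frac, event_frac = _FLANK_EVENT_FRACTIONS[call.copy_state]
    if call.copy_state is CopyState.DUP:
        flank_like = depth <= med * flank_frac
        event_like = depth >= med * event_frac
    else:
        flank_like = depth >= med * flank_frac
        event_like = depth < med * event_frac

    mid = (start + end) // 2

    def fallback(side: str) -> tuple[int, int]:
        if intron_bounds is not None:
            return intron_bounds[0] if side == "left" else intron_bounds[1]
        return (int(positions[0]), start) if side == "left" else (end, int(positions[-1]))

    # left: last flank-like base before the event, first event-like after it
    sel = positions <= mid
    pos = positions[sel]
    f_idx = np.nonzero(flank_like[sel])[0]
    if f_idx.size:
        e_idx = np.nonzero(event_like[sel])[0]
        e_idx = e_idx[e_idx > f_idx[-1]]
        left = (
            (int(pos[f_idx[-1]]) + 1, int(pos[e_idx[0]])) if e_idx.size else fallback("left")
        )
    else:
        left = fallback("left")

    # right: mirrored
    sel = positions >= mid
    pos = positions[sel]
    f_idx = np.nonzero(flank_like[sel])[0]
    if f_idx.size:
        e_idx = np.nonzero(event_like[sel])[0]
        e_idx = e_idx[e_idx < f_idx[0]]
        right = (
            (int(pos[e_idx[-1]]), int(pos[f_idx[0]]) - 1) if e_idx.size else fallback("right")
        )
    else:
        right = fallback("right")

    if intron_bounds is not None:
        (llo, lhi), (rlo, rhi) = intron_bounds
        left = (max(left[0], llo), min(left[1], lhi))
        right = (max(right[0], rlo), min(right[1], rhi))
    return left, right


def junction_product_size(
    left_primer_start: int,
    right_primer_end: int,
    deletion: tuple[int, int] | None,
) -> int:
    """Junction-PCR product size across a deletion.

    ``left_primer_start`` is the 5' genomic coordinate of the forward
    primer, ``right_primer_end`` the 3' coordinate of the reverse primer
    (both 1-based on the reference, flanking the deletion).  The product
    equals the undeleted template span minus the deleted length::

        product = (right_primer_end - left_primer_start + 1) - deletion_bp

    e.g. a 107,720 bp template span across a 107,468 bp deletion yields
    the 252 bp carrier-specific product.  With ``deletion=None`` (intact
    allele) the product is the full template span.
    """
    if right_primer_end <= left_primer_start:
        raise ValueError("right primer must lie downstream of left primer")
    if deletion is None:
        return right_primer_end - left_primer_start + 1
    del_start, del_end = deletion
    if not (left_primer_start < del_start and right_primer_end > del_end):
        raise ValueError("primers must flank the deletion on the reference")
    template = right_primer_end - left_primer_start + 1
    bp, _ = deletion_length(del_start, del_end)
    product = template - bp
    if product <= 0:
        raise ValueError("primers do not leave a positive junction product")
    return product
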