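"""Runs of homozygosity: calling, totals, cross-patient sharing, containment.

The caller scans a biallelic marker track with a sliding window of
``window_markers`` markers and at most ``max_het_per_window``
heterozygous calls per window.  A candidate segment is an
inclusion-maximal run of at least ``window_markers`` markers in which
every fully contained window passes; runs shorter than one window carry
no window-level evidence and are never called.  Candidate boundaries are
then trimmed to the outermost homozygous markers (stable under window-
size changes), segments separated by less than ``stitch_gap_bp`` are
stitched (a handful of genotyping errors inside a long autozygous block
otherwise splits it), and the result is filtered by minimum physical
length and marker support.

Missing genotypes are treated as non-heterozygous (they neither support
nor break a run) but do not count as homozygous boundary markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import (
    GT_AA,
    GT_BB,
    MarkerTrack,
    RohSegment,
    VariantRecord,
)

__all__ = [
    "RohParams",
    "call_roh",
    "call_roh_bruteforce",
    "total_autozygosity",
    "shared_roh",
    "SharedRegion",
    "variant_in_roh",
    "autozygosity_by_genotype_class",
]


@dataclass(frozen=True)
class RohParams:
    window_markers: int = 50
    max_het_per_window: int = 1
    min_length_bp: int = 1_000_000
    min_markers: int = 25
    stitch_gap_bp: int = 500_000

    def __post_init__(self) -> None:
        for name in (
            "window_markers",
            "min_length_bp",
            "min_markers",
            "stitch_gap_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het_per_window < 0:
            raise ValueError("max_het_per_window must be >= 0")


def _candidate_runs(het: np.ndarray, w: int, h: int) -> list[tuple[int, int]]:
    """Inclusion-maximal marker runs (>= w markers) whose windows all pass."""
    n = het.size
    if n < w:
        return []
    window_sums = np.convolve(het.astype(np.int64), np.ones(w, dtype=np.int64), "valid")
    ok = window_sums <= h  # ok[i] == window starting at marker i passes
    runs: list[tuple[int, int]] = []
    i = 0
    m = ok.size
    while i < m:
        if ok[i]:
            j = i
            while j + 1 < m and ok[j + 1]:
                j += 1
            runs.append((i, j + w - 1))
            i = j + 1
        else:
            i += 1
    return runs


def _trim_to_hom(genotypes: np.ndarray, a: int, b: int) -> tuple[int, int] | None:
    hom = (genotypes == GT_AA) | (genotypes == GT_BB)
    idx = np.nonzero(hom[a : b + 1])[0]
    if idx.size == 0:
        return None
    return a + int(idx[0]), a + int(idx[-1])


def call_roh(track: MarkerTrack, params: RohParams = RohParams()) -> list[RohSegment]:
    """Call ROH segments on one chromosome of one patient."""
    if track.positions.size and np.any(np.diff(track.positions) <= 0):
        raise ValueError("marker positions must be sorted and unique")
    het = track.het_mask()
    runs = _candidate_runs(het, params.window_markers, params.max_het_per_window)

    trimmed: list[tuple[int, int]] = []
    for a, b in runs:
        t = _trim_to_hom(track.genotypes, a, b)
        if t is not None:
            trimmed.append(t)

    # stitch marker-index runs whose physical gap is below stitch_gap_bp
    stitched: list[tuple[int, int]] = []
    for a, b in trimmed:
        if stitched:
            pa, pb = stitched[-1]
            gap = track.positions[a] - track.positions[pb] - 1
            if gap < params.stitch_gap_bp:
                stitched[-1] = (pa, b)
                continue
        stitched.append((a, b))

    segments: list[RohSegment] = []
    for a, b in stitched:
        start = int(track.positions[a])
        end = int(track.positions[b])
        n_markers = b - a + 1
        if end - start + 1 < params.min_length_bp or n_markers < params.min_markers:
            continue
        segments.append(
            RohSegment(
                patient_id=track.patient_id,
                chrom=track.chrom,
                start=start,
                end=end,
                n_markers=n_markers,
                n_het=int(het[a : b + 1].sum()),
            )
        )
    return segments


def call_roh_bruteforce(
    track: MarkerTrack, params: RohParams = RohParams()
) -> list[RohSegment]:
    """O(n²) reference implementation of the same segment definition.

    Enumerates every marker interval of at least ``window_markers``
    markers, keeps those in which all contained windows pass, takes the
    inclusion-maximal ones, then applies the identical trim/stitch/filter
    steps.  Used as the oracle in property tests; only viable for small
    tracks.
    """
    het = track.het_mask().astype(int)
    n = het.size
    w, h = params.window_markers, params.max_het_per_window
    valid: list[tuple[int, int]] = []
    for a in range(n):
        for b in range(a + w - 1, n):
            ok = all(het[i : i + w].sum() <= h for i in range(a, b - w + 2))
            if ok:
                valid.append((a, b))
    maximal = [
        (a, b)
        for a, b in valid
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in valid)
    ]
    maximal.sort()

    trimmed = []
    for a, b in maximal:
        t = _trim_to_hom(track.genotypes, a, b)
        if t is not None:
            trimmed.append(t)
    stitched: list[tuple[int, int]] = []
    for a, b in trimmed:
        if stitched:
            pa, pb = stitched[-1]
            if track.positions[a] - track.positions[pb] - 1 < params.stitch_gap_bp:
                stitched[-1] = (pa, b)
                continue
        stitched.append((a, b))
    out = []
    for a, b in stitched:
        start, end = int(track.positions[a]), int(track.positions[b])
        n_markers = b - a + 1
        if end - start + 1 < params.min_length_bp or n_markers < params.min_markers:
            continue
        out.append(
            RohSegment(
                patient_id=track.patient_id,
                chrom=track.chrom,
                start=start,
                end=end,
                n_markers=n_markers,
                n_het=int(het[a : b + 1].sum()),
            )
        )
    return out


def total_autozygosity(
    segments: Iterable[RohSegment], *, exclude_chroms: Sequence[str] = ("X", "Y")
) -> float:
    """Total autozygosity in megabases: Σ segment length / 10⁶.

    Sex chromosomes are excluded by default (male hemizygosity is not
    autozygosity).  Overlapping segments on one chromosome are an error.
    """
    segs = [s for s in segments if s.chrom not in exclude_chroms]
    by_chrom: dict[str, list[RohSegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ss in by_chrom.items():
        ss.sort(key=lambda s: s.start)
        for s1, s2 in zip(ss, ss[1:]):
            if s2.start <= s1.end:
                raise ValueError(f"overlapping ROH segments on chromosome {chrom}")
    return sum(s.length_bp for s in segs) / 1e6


@dataclass(frozen=True)
class SharedRegion:
    """A maximal interval covered by the ROHs of >= min_patients patients."""

    chrom: str
    start: int
    end: int
    patients: tuple[str, ...]
    #: intersection of the supporting patients' overlapping segments
    minimal_critical_region: tuple[int, int]

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def shared_roh(
    segment_sets: dict[str, list[RohSegment]],
    min_patients: int,
) -> list[SharedRegion]:
    """Sweep-line detection of intervals shared by many patients' ROHs.

    For every chromosome, returns the maximal intervals at which at least
    ``min_patients`` distinct patients have an overlapping ROH, together
    with the minimal critical region — the intersection of the supporting
    patients' segments, the natural localization of a founder allele.
    """
    if min_patients < 2:
        raise ValueError("min_patients must be >= 2")
    if len(segment_sets) < 2:
        raise ValueError("shared_roh needs at least two patients")

    all_segs: list[RohSegment] = [s for segs in segment_sets.values() for s in segs]
    regions: list[SharedRegion] = []
    for chrom in sorted({s.chrom for s in all_segs}):
        events: list[tuple[int, int]] = []
        chrom_segs = [s for s in all_segs if s.chrom == chrom]
        for s in chrom_segs:
            events.append((s.start, +1))
            events.append((s.end + 1, -1))
        events.sort()
        depth = 0
        open_start: int | None = None
        intervals: list[tuple[int, int]] = []
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth >= min_patients and open_start is None:
                open_start = pos
            elif depth < min_patients and open_start is not None:
                intervals.append((open_start, pos - 1))
                open_start = None
        for start, end in intervals:
            support = {}
            for s in chrom_segs:
                if s.start <= end and s.end >= start:
                    # keep the widest overlapping segment per patient
                    cur = support.get(s.patient_id)
                    if cur is None or s.length_bp > cur.length_bp:
                        support[s.patient_id] = s
            mcr = (
                max(s.start for s in support.values()),
                min(s.end for s in support.values()),
            )
            regions.append(
                SharedRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    patients=tuple(sorted(support)),
                    minimal_critical_region=mcr,
                )
            )
    return regions


def variant_in_roh(variant: VariantRecord, segments: Iterable[RohSegment]) -> bool:
    """True iff the variant's interval is fully contained in some segment."""
    return any(
        s.chrom == variant.chrom and s.contains(variant.start, variant.end)
        for s in segments
    )


def _lower_median(values: list[float]) -> float:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def autozygosity_by_genotype_class(
    totals_by_patient: dict[str, float],
    genotype_class_by_patient: dict[str, str],
) -> dict[str, dict[str, float]]:
    """Median (lower-median convention) and quartiles of total autozygosity
    per genotype class (AR-hom, AR-comp-het, AD-het, XL-hemi, unsolved).

    Empty classes are omitted.  Output is independent of patient order.
    """
    by_class: dict[str, list[float]] = {}
    for pid, cls in genotype_class_by_patient.items():
        if pid in totals_by_patient:
            by_class.setdefault(cls, []).append(totals_by_patient[pid])
    out: dict[str, dict[str, float]] = {}
    for cls in sorted(by_class):
        vals = np.sort(np.asarray(by_class[cls], dtype=float))
        out[cls] = {
            "n": float(vals.size),
            "q1": float(np.percentile(vals, 25)),
            "median": _lower_median(list(vals)),
            "q3": float(np.percentile(vals, 75)),
        }
    return out
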