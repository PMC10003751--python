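"""Domain types shared by every stage of the pipeline.

Coordinate convention: all genomic intervals are 1-based and inclusive at
both ends (HGVS style), matching deletion arithmetic such as
``g.65665873_65773340del``.  Conversion to BED's 0-based half-open
convention happens only at the IO boundary (:mod:`irdscape.io`).
Chromosome names are stored without a ``chr`` prefix.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariantKind",
    "MolecularProfile",
    "ClinicalClass",
    "Zygosity",
    "Phase",
    "Sex",
    "Inheritance",
    "DiagnosticStatus",
    "VariantRecord",
    "GenotypeCall",
    "PatientRecord",
    "MarkerTrack",
    "RohSegment",
    "CoverageMatrix",
    "CnvCall",
    "GT_AA",
    "GT_AB",
    "GT_BB",
    "GT_MISSING",
    "GT_CODES",
    "GT_LABELS",
]


class VariantKind(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"
    CNV_DEL = "cnv_del"
    CNV_DUP = "cnv_dup"
    MEI = "mei"


class MolecularProfile(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    START_LOSS = "start_loss"
    STRUCTURAL = "structural"


class ClinicalClass(str, enum.Enum):
    """ACMG-style five-tier clinical classification."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"

    @property
    def is_plp(self) -> bool:
        return self in (ClinicalClass.P, ClinicalClass.LP)


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Phase(str, enum.Enum):
    IN_TRANS = "in_trans"
    IN_CIS = "in_cis"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Inheritance(str, enum.Enum):
    """Mode of inheritance as ascertained from family history."""

    ISOLATED = "isolated"
    AR = "AR"
    AD = "AD"
    XL = "XL"
    UNKNOWN = "unknown"

    @property
    def recessive_context(self) -> bool:
        """Modes handled under the recessive decision rules.

        Isolated cases follow the recessive rules; the single proband with
        unascertainable inheritance is treated the same way.
        """
        return self in (Inheritance.ISOLATED, Inheritance.AR, Inheritance.UNKNOWN)


class DiagnosticStatus(str, enum.Enum):
    SOLVED = "solved"
    LIKELY_SOLVED = "likely_solved"
    UNCERTAIN = "uncertain"
    UNSOLVED = "unsolved"


#: Ordering used by the monotone-upgrade property: promoting a VUS to LP may
#: only move a patient up this ladder.
STATUS_ORDER = {
    DiagnosticStatus.UNSOLVED: 0,
    DiagnosticStatus.UNCERTAIN: 1,
    DiagnosticStatus.LIKELY_SOLVED: 2,
    DiagnosticStatus.SOLVED: 3,
}


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class VariantRecord:
    """One distinct variant (SNV, indel or CNV) with its annotations.

    ``start``/``end`` are 1-based inclusive; ``start == end`` for SNVs.
    ``splice_score`` houses a dbscSNV-ADA-style splice prediction in [0, 1].
    ``ref``/``alt`` are empty strings for symbolic CNV records.
    """

    variant_id: str
    gene: str
    chrom: str
    start: int
    end: int
    ref: str = ""
    alt: str = ""
    kind: VariantKind = VariantKind.SNV
    profile: MolecularProfile = MolecularProfile.MISSENSE
    maf: float | None = None
    gerp: float | None = None
    splice_score: float | None = None
    clinical_class: ClinicalClass = ClinicalClass.VUS
    novel: bool = False

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom).removeprefix("chr")
        self.kind = VariantKind(self.kind)
        self.profile = MolecularProfile(self.profile)
        self.clinical_class = ClinicalClass(self.clinical_class)
        if self.start > self.end:
            raise ValueError(
                f"{self.variant_id}: start {self.start} > end {self.end}"
            )
        if not _is_missing(self.maf) and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 1]")
        if self.kind in (VariantKind.CNV_DEL, VariantKind.CNV_DUP):
            if self.profile is not MolecularProfile.STRUCTURAL:
                raise ValueError(
                    f"{self.variant_id}: CNV records must have profile=structural"
                )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenotypeCall:
    """A patient × variant observation with zygosity and phase evidence."""

    patient_id: str
    variant_id: str
    zygosity: Zygosity
    phase_partner: str | None = None
    phase: Phase = Phase.NOT_APPLICABLE

    def __post_init__(self) -> None:
        self.zygosity = Zygosity(self.zygosity)
        self.phase = Phase(self.phase)
        if self.zygosity in (Zygosity.HOM, Zygosity.HEMI):
            if self.phase is not Phase.NOT_APPLICABLE:
                raise ValueError(
                    f"{self.patient_id}/{self.variant_id}: hom/hemi calls "
                    "carry phase=not_applicable"
                )


@dataclass
class PatientRecord:
    """Index-case metadata plus (eventually) the assigned diagnostic status."""

    patient_id: str
    sex: Sex
    inheritance: Inheritance
    phenotype_class: str = "other"
    birth_year: int | None = None
    status: DiagnosticStatus | None = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.inheritance = Inheritance(self.inheritance)
        if self.status is not None:
            self.status = DiagnosticStatus(self.status)


# Integer genotype codes for biallelic marker tracks.
GT_AA, GT_AB, GT_BB, GT_MISSING = 0, 1, 2, -1
GT_CODES = {"AA": GT_AA, "AB": GT_AB, "BB": GT_BB, "missing": GT_MISSING}
GT_LABELS = {v: k for k, v in GT_CODES.items()}


@dataclass
class MarkerTrack:
    """Biallelic marker genotypes along one chromosome of one patient.

    ``positions`` is strictly increasing (1-based); ``genotypes`` holds the
    integer codes ``GT_AA``/``GT_AB``/``GT_BB``/``GT_MISSING``.
    """

    patient_id: str
    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom).removeprefix("chr")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.positions.shape != self.genotypes.shape:
            raise ValueError("positions and genotypes must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)

    def het_mask(self) -> np.ndarray:
        return self.genotypes == GT_AB


@dataclass
class RohSegment:
    """A called run of homozygosity (1-based inclusive coordinates)."""

    patient_id: str
    chrom: str
    start: int
    end: int
    n_markers: int
    n_het: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("RohSegment start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class CoverageMatrix:
    """Per-exon sequencing depth for a cohort.

    ``exons`` is a list of ``(gene, exon_number, chrom, start, end)`` tuples;
    ``depth`` has shape (n_exons, n_samples) with non-negative entries.
    """

    exons: list[tuple[str, int, str, int, int]]
    samples: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.exons), len(self.samples)):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.exons)} exons x {len(self.samples)} samples"
            )
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")
        by_gene: dict[str, list[tuple[int, int]]] = {}
        for gene, _num, _chrom, start, end in self.exons:
            by_gene.setdefault(gene, []).append((start, end))
        for gene, ivals in by_gene.items():
            ivals.sort()
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping exon intervals in gene {gene}")


class CopyState(str, enum.Enum):
    HOM_DEL = "hom_del"
    HET_DEL = "het_del"
    DUP = "dup"


@dataclass
class CnvCall:
    """A called copy-number event spanning one or more consecutive exons.

    Breakpoint intervals are 1-based inclusive uncertainty bounds in the
    flanking introns (or flanking intergenic sequence at gene ends).
    """

    patient_id: str
    gene: str
    first_exon: int
    last_exon: int
    copy_state: CopyState
    breakpoint_left: tuple[int, int] = field(default=(0, 0))
    breakpoint_right: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        self.copy_state = CopyState(self.copy_state)
        if self.first_exon > self.last_exon:
            raise ValueError("first_exon > last_exon")

    @property
    def n_exons(self) -> int:
        return self.last_exon - self.first_exon + 1
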