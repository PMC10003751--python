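"""Patient-level decision procedure: genotype assortment → diagnostic status.

A patient's best candidate genotype in a single gene is summarized as an
*assortment*: either one variant (heterozygous, homozygous or hemizygous)
or a pair of heterozygous variants with a phase relation.  The rules map
the assortment, together with the mode of inheritance and the patient's
sex, to one of four statuses::

    solved         AD + het P/LP; recessive/isolated + biallelic P/LP
                   (comp-het in trans, or homozygous); XL male + hemi P/LP
    likely_solved  recessive + (P/LP with VUS in trans), or two P/LP with
                   unknown phase
    uncertain      recessive + VUS-containing configurations (two VUS in
                   trans, P/LP+VUS phase unknown, two VUS phase unknown,
                   homozygous VUS); AD + het VUS; XL male + hemi VUS
    unsolved       everything else, including a single heterozygous P/LP
                   in a recessive context and any in-cis pair

Isolated cases (and the rare proband whose inheritance could not be
ascertained) are handled under the recessive rules.  A homozygous P/LP is
treated as two alleles in trans.  Manifesting X-linked heterozygous
females are not covered by the written rules; the policy is configurable
and defaults to ``solved``, with the affected patients flagged in pipeline
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .model import (
    ClinicalClass,
    DiagnosticStatus,
    GenotypeCall,
    Inheritance,
    PatientRecord,
    Phase,
    Sex,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "AssortmentEntry",
    "GenotypeAssortment",
    "classify_patient",
    "diagnose_cohort",
    "diagnostic_yield",
    "YieldSummary",
    "round_percent",
]


@dataclass(frozen=True)
class AssortmentEntry:
    clinical_class: ClinicalClass
    zygosity: Zygosity
    phase: Phase = Phase.NOT_APPLICABLE

    def __post_init__(self) -> None:
        object.__setattr__(self, "clinical_class", ClinicalClass(self.clinical_class))
        object.__setattr__(self, "zygosity", Zygosity(self.zygosity))
        object.__setattr__(self, "phase", Phase(self.phase))


@dataclass(frozen=True)
class GenotypeAssortment:
    """At most two variants within the top candidate gene of one patient."""

    inheritance: Inheritance
    sex: Sex
    entries: tuple[AssortmentEntry, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "inheritance", Inheritance(self.inheritance))
        object.__setattr__(self, "sex", Sex(self.sex))
        if len(self.entries) > 2:
            raise ValueError("an assortment holds at most 2 distinct variants")
        for e in self.entries:
            if e.clinical_class in (ClinicalClass.B, ClinicalClass.LB):
                raise ValueError("benign variants do not enter assortments")
            if e.zygosity in (Zygosity.HOM, Zygosity.HEMI) and e.phase is not Phase.NOT_APPLICABLE:
                raise ValueError("hom/hemi entries must have phase=not_applicable")
            if e.zygosity is Zygosity.HEMI and self.sex is Sex.FEMALE:
                raise ValueError("hemizygous call in a female patient")
        if len(self.entries) == 2:
            if any(e.zygosity is not Zygosity.HET for e in self.entries):
                raise ValueError("a variant pair must consist of two heterozygous calls")
            if self.entries[0].phase != self.entries[1].phase:
                raise ValueError("phase must be symmetric between partners")
            if self.entries[0].phase is Phase.NOT_APPLICABLE:
                raise ValueError("a variant pair must carry a phase relation")


def classify_patient(
    assortment: GenotypeAssortment,
    *,
    xl_female_het_plp: DiagnosticStatus = DiagnosticStatus.SOLVED,
) -> DiagnosticStatus:
    """Apply the status rules to one assortment; exactly one rule fires."""
    inh = assortment.inheritance
    entries = assortment.entries
    rec = inh.recessive_context
    plp = [e for e in entries if e.clinical_class.is_plp]
    vus = [e for e in entries if e.clinical_class is ClinicalClass.VUS]

    if len(entries) == 1:
        (e,) = entries
        is_plp = e.clinical_class.is_plp
        if inh is Inheritance.AD and e.zygosity is Zygosity.HET:
            return (
                DiagnosticStatus.SOLVED if is_plp else DiagnosticStatus.UNCERTAIN
            )
        if rec and e.zygosity is Zygosity.HOM:
            # homozygosity implies two alleles in trans
            return (
                DiagnosticStatus.SOLVED if is_plp else DiagnosticStatus.UNCERTAIN
            )
        if inh is Inheritance.XL and e.zygosity is Zygosity.HEMI:
            return (
                DiagnosticStatus.SOLVED if is_plp else DiagnosticStatus.UNCERTAIN
            )
        if inh is Inheritance.XL and assortment.sex is Sex.FEMALE and e.zygosity is Zygosity.HET:
            return xl_female_het_plp if is_plp else DiagnosticStatus.UNCERTAIN
        return DiagnosticStatus.UNSOLVED

    if len(entries) == 2 and rec:
        phase = entries[0].phase
        if phase is Phase.IN_CIS:
            return DiagnosticStatus.UNSOLVED
        if phase is Phase.IN_TRANS:
            if len(plp) == 2:
                return DiagnosticStatus.SOLVED
            if len(plp) == 1 and len(vus) == 1:
                return DiagnosticStatus.LIKELY_SOLVED
            return DiagnosticStatus.UNCERTAIN  # two VUS in trans
        # phase unknown
        if len(plp) == 2:
            return DiagnosticStatus.LIKELY_SOLVED
        return DiagnosticStatus.UNCERTAIN  # PLP+VUS or two VUS, phase unknown

    return DiagnosticStatus.UNSOLVED


def round_percent(fraction: float) -> int:
    """Round a fraction to an integer percent, half-up (174/230 → 76)."""
    return int(
        (Decimal(str(fraction)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class YieldSummary:
    n_total: int
    counts: dict[DiagnosticStatus, int]
    yield_fraction: float
    by_phenotype: dict[str, float] = field(default_factory=dict)

    @property
    def yield_percent(self) -> int:
        return round_percent(self.yield_fraction)


def diagnostic_yield(patients: list[PatientRecord]) -> YieldSummary:
    """Diagnostic yield = (solved + likely_solved) / all index patients."""
    if not patients:
        raise ValueError("diagnostic_yield of an empty cohort is undefined")
    for p in patients:
        if p.status is None:
            raise ValueError(f"patient {p.patient_id} has no diagnostic status")
    counts = {s: 0 for s in DiagnosticStatus}
    for p in patients:
        counts[p.status] += 1
    diagnosed = counts[DiagnosticStatus.SOLVED] + counts[DiagnosticStatus.LIKELY_SOLVED]
    by_pheno: dict[str, float] = {}
    for pheno in sorted({p.phenotype_class for p in patients}):
        members = [p for p in patients if p.phenotype_class == pheno]
        d = sum(
            1
            for p in members
            if p.status in (DiagnosticStatus.SOLVED, DiagnosticStatus.LIKELY_SOLVED)
        )
        by_pheno[pheno] = d / len(members)
    return YieldSummary(
        n_total=len(patients),
        counts=counts,
        yield_fraction=diagnosed / len(patients),
        by_phenotype=by_pheno,
    )


def diagnose_cohort(
    patients: list[PatientRecord],
    variants: list[VariantRecord],
    genotypes: list[GenotypeCall],
    *,
    xl_female_het_plp: DiagnosticStatus = DiagnosticStatus.SOLVED,
) -> tuple[list[PatientRecord], dict[str, GenotypeAssortment | None]]:
    """Classify every patient from their candidate genotype configurations.

    For each patient the candidate configurations compatible with the
    inheritance mode (see :func:`irdscape.prioritize.inheritance_candidates`)
    are classified and the best status is kept, breaking ties in favour of
    the lower gene tier ordering already applied by the candidate
    generator.  Returns the patients with ``status`` set, plus the winning
    assortment per patient (``None`` when there was no candidate).
    """
    from .model import STATUS_ORDER
    from .prioritize import inheritance_candidates

    vmap = {v.variant_id: v for v in variants}
    by_patient: dict[str, list[GenotypeCall]] = {}
    for g in genotypes:
        by_patient.setdefault(g.patient_id, []).append(g)

    winning: dict[str, GenotypeAssortment | None] = {}
    for p in patients:
        best = DiagnosticStatus.UNSOLVED
        best_assort: GenotypeAssortment | None = None
        for cand in inheritance_candidates(p, by_patient.get(p.patient_id, []), vmap):
            entries = tuple(
                AssortmentEntry(
                    clinical_class=vmap[g.variant_id].clinical_class,
                    zygosity=g.zygosity,
                    phase=g.phase,
                )
                for g in cand
            )
            assortment = GenotypeAssortment(
                inheritance=p.inheritance, sex=p.sex, entries=entries
            )
            status = classify_patient(assortment, xl_female_het_plp=xl_female_het_plp)
            if STATUS_ORDER[status] > STATUS_ORDER[best]:
                best, best_assort = status, assortment
        p.status = best
        winning[p.patient_id] = best_assort
    return patients, winning
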