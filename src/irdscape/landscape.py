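"""Cohort-level summary statistics.

Per-gene prevalence among diagnosed cases, the allele-recurrence
spectrum (how often each causative variant recurs across index
patients), the zygosity/inheritance breakdown of diagnosed genotypes,
variant-class counts, and birth-cohort trends of autozygosity.

Allele occurrences count allele copies over index patients only: a
homozygote contributes two, a heterozygous or hemizygous carrier one —
so eight homozygotes plus one heterozygote give 17 occurrences of a
variant.  The recurrence spectrum supports two denominators (distinct
variants, or total causative alleles); both are reported because either
convention is defensible.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnose import GenotypeAssortment
from .model import (
    DiagnosticStatus,
    GenotypeCall,
    PatientRecord,
    Sex,
    VariantKind,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "GenotypeClass",
    "allele_occurrences",
    "recurrence_spectrum",
    "gene_prevalence",
    "zygosity_breakdown",
    "genotype_class",
    "variant_class_counts",
    "birth_cohort_trend",
    "CohortSummary",
    "summarize_cohort",
]

DIAGNOSED = (DiagnosticStatus.SOLVED, DiagnosticStatus.LIKELY_SOLVED)


class GenotypeClass(str, enum.Enum):
    AR_HOM = "AR_hom"
    AR_COMP_HET = "AR_comp_het"
    AD_HET = "AD_het"
    XL_HEMI = "XL_hemi"
    XL_HET_FEMALE = "XL_het_female"


def allele_occurrences(variant_id: str, genotypes: list[GenotypeCall]) -> int:
    """Allele copies of one variant over the supplied causative calls."""
    n = 0
    for g in genotypes:
        if g.variant_id != variant_id:
            continue
        n += 2 if g.zygosity is Zygosity.HOM else 1
    return n


def recurrence_spectrum(
    variants: list[VariantRecord],
    genotypes: list[GenotypeCall],
    denominator: str = "distinct_variants",
) -> dict[str, float]:
    """Fractions of variants (or alleles) seen once, twice, three-plus times.

    ``denominator='distinct_variants'`` divides bin counts by the number
    of distinct recurring variants; ``'alleles'`` weights each variant by
    its occurrence count.  Variants with zero occurrences are ignored.
    """
    if denominator not in ("distinct_variants", "alleles"):
        raise ValueError(f"unknown denominator {denominator!r}")
    occ = {
        v.variant_id: allele_occurrences(v.variant_id, genotypes) for v in variants
    }
    occ = {k: n for k, n in occ.items() if n > 0}
    if not occ:
        raise ValueError("no variant has any occurrence")
    bins = {"once": 0.0, "twice": 0.0, "three_plus": 0.0}
    for n in occ.values():
        key = "once" if n == 1 else "twice" if n == 2 else "three_plus"
        bins[key] += 1 if denominator == "distinct_variants" else n
    total = sum(bins.values())
    return {k: v / total for k, v in bins.items()}


def gene_prevalence(
    patients: list[PatientRecord],
    causal_gene: dict[str, str],
    *,
    group_small: bool = False,
    small_max: int = 2,
) -> pd.DataFrame:
    """Counts and percentages per disease gene over diagnosed index cases.

    ``causal_gene`` maps patient_id -> gene for diagnosed patients.
    With ``group_small``, genes seen in at most ``small_max`` patients
    collapse into an "other" row.
    """
    diagnosed = [p for p in patients if p.status in DIAGNOSED]
    rows = [
        (p.patient_id, causal_gene[p.patient_id])
        for p in diagnosed
        if p.patient_id in causal_gene
    ]
    if not rows:
        return pd.DataFrame(columns=["gene", "n_index_cases", "percent"])
    df = pd.DataFrame(rows, columns=["patient_id", "gene"])
    counts = df.groupby("gene").size().sort_values(ascending=False)
    if group_small:
        small = counts[counts <= small_max]
        if len(small):
            counts = counts[counts > small_max]
            counts["other"] = small.sum()
    out = counts.rename("n_index_cases").reset_index()
    out["percent"] = out["n_index_cases"] / len(diagnosed) * 100
    return out


def genotype_class(
    patient: PatientRecord, assortment: GenotypeAssortment
) -> GenotypeClass:
    """Assign one diagnosed genotype to its zygosity/inheritance class."""
    entries = assortment.entries
    if assortment.inheritance.recessive_context:
        if len(entries) == 1 and entries[0].zygosity is Zygosity.HOM:
            return GenotypeClass.AR_HOM
        if len(entries) == 2:
            return GenotypeClass.AR_COMP_HET
    elif assortment.inheritance.value == "AD":
        if len(entries) == 1 and entries[0].zygosity is Zygosity.HET:
            return GenotypeClass.AD_HET
    else:  # XL
        if len(entries) == 1 and entries[0].zygosity is Zygosity.HEMI:
            return GenotypeClass.XL_HEMI
        if (
            len(entries) == 1
            and entries[0].zygosity is Zygosity.HET
            and patient.sex is Sex.FEMALE
        ):
            return GenotypeClass.XL_HET_FEMALE
    raise ValueError(
        f"patient {patient.patient_id}: genotype configuration not classifiable "
        f"({assortment.inheritance.value}, {[e.zygosity.value for e in entries]})"
    )


def zygosity_breakdown(
    patients: list[PatientRecord],
    assortments: dict[str, GenotypeAssortment],
) -> dict[GenotypeClass, float]:
    """Fractions of diagnosed patients per genotype class."""
    diagnosed = [p for p in patients if p.status in DIAGNOSED]
    if not diagnosed:
        raise ValueError("no diagnosed patients")
    counts = {c: 0 for c in GenotypeClass}
    for p in diagnosed:
        a = assortments.get(p.patient_id)
        if a is None:
            raise ValueError(f"diagnosed patient {p.patient_id} lacks an assortment")
        counts[genotype_class(p, a)] += 1
    return {c: n / len(diagnosed) for c, n in counts.items()}


def variant_class_counts(
    variants: list[VariantRecord], genotypes: list[GenotypeCall]
) -> dict[VariantKind, tuple[int, int]]:
    """Per variant kind: (distinct variants, total allele occurrences)."""
    out: dict[VariantKind, tuple[int, int]] = {}
    for kind in VariantKind:
        members = [v for v in variants if v.kind is kind]
        occs = [allele_occurrences(v.variant_id, genotypes) for v in members]
        present = [(v, n) for v, n in zip(members, occs) if n > 0]
        if present:
            out[kind] = (len(present), sum(n for _v, n in present))
    return out


def birth_cohort_trend(
    patients: list[PatientRecord],
    roh_totals: dict[str, float],
    hom_class: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-decade medians of total autozygosity and % homozygous genotypes.

    ``roh_totals`` maps patient_id -> total autozygosity (Mb);
    ``hom_class`` maps diagnosed patient_id -> True when the causative
    genotype is homozygous.  Patients without a birth year are excluded
    (their count is reported via a warning).
    """
    with_year = [p for p in patients if p.birth_year is not None]
    missing = len(patients) - len(with_year)
    if missing:
        warnings.warn(f"excluding {missing} patient(s) without birth year", stacklevel=2)
    if not with_year:
        warnings.warn("no birth years available; empty trend table", stacklevel=2)
        return pd.DataFrame(
            columns=["decade", "n", "median_autozygosity_mb", "percent_hom"]
        )
    rows = []
    for p in with_year:
        rows.append(
            {
                "patient_id": p.patient_id,
                "decade": (p.birth_year // 10) * 10,
                "autozygosity": roh_totals.get(p.patient_id, np.nan),
                "hom": (
                    hom_class.get(p.patient_id)
                    if hom_class is not None and p.patient_id in hom_class
                    else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for decade, grp in df.groupby("decade"):
        az = grp["autozygosity"].dropna()
        hom = grp["hom"].dropna()
        out.append(
            {
                "decade": int(decade),
                "n": len(grp),
                "median_autozygosity_mb": float(az.median()) if len(az) else np.nan,
                "percent_hom": float(hom.mean() * 100) if len(hom) else np.nan,
            }
        )
    return pd.DataFrame(out).sort_values("decade").reset_index(drop=True)


@dataclass
class CohortSummary:
    yield_fraction: float
    yield_percent: int
    per_gene: pd.DataFrame
    recurrence_distinct: dict[str, float]
    recurrence_alleles: dict[str, float]
    zygosity: dict[GenotypeClass, float]
    variant_classes: dict[VariantKind, tuple[int, int]]
    n_index: int = 0
    extra: dict = field(default_factory=dict)


def summarize_cohort(
    patients: list[PatientRecord],
    variants: list[VariantRecord],
    causative_calls: list[GenotypeCall],
    assortments: dict[str, GenotypeAssortment],
    causal_gene: dict[str, str],
) -> CohortSummary:
    """One-stop summary mirroring the per-gene, recurrence, zygosity and
    yield views of a diagnosed cohort."""
    from .diagnose import diagnostic_yield

    ysum = diagnostic_yield(patients)
    return CohortSummary(
        yield_fraction=ysum.yield_fraction,
        yield_percent=ysum.yield_percent,
        per_gene=gene_prevalence(patients, causal_gene),
        recurrence_distinct=recurrence_spectrum(variants, causative_calls, "distinct_variants"),
        recurrence_alleles=recurrence_spectrum(variants, causative_calls, "alleles"),
        zygosity=zygosity_breakdown(patients, assortments),
        variant_classes=variant_class_counts(variants, causative_calls),
        n_index=len(patients),
    )
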