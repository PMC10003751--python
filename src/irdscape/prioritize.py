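"""Variant prioritization cascade and the VUS retention gate.

The cascade keeps a variant when it passes, independently, a molecular-
profile filter, a population-frequency filter and — for variants of
unknown significance — a stricter retention gate requiring rarity,
protein-level (or splice-predicted) impact, and evolutionary conservation
(GERP > 4) or a strong splice prediction.  Candidate genotype
configurations are then formed per patient according to the compatible
inheritance pattern, and reported by gene tier: disease-gene panel first
(tier 1, "RetNet"-style), then phenotype-database genes (tier 2, "OMIM"-
style), then the rest of the genome (tier 3).

Missing annotations: a missing MAF passes the frequency filters (a novel
variant has no population record), while a missing GERP fails the VUS
conservation arm and a missing splice score fails any splice-based
rescue.  A synonymous variant is kept only on splice-prediction evidence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations

from .model import (
    ClinicalClass,
    GenotypeCall,
    Inheritance,
    MolecularProfile,
    PatientRecord,
    Phase,
    Sex,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "PrioritizationConfig",
    "profile_filter",
    "frequency_filter",
    "vus_retention",
    "gene_tier",
    "inheritance_candidates",
    "prioritize_variants",
]

DEFAULT_PROFILES = frozenset(
    {
        MolecularProfile.NONSENSE,
        MolecularProfile.FRAMESHIFT,
        MolecularProfile.MISSENSE,
        MolecularProfile.SPLICE_REGION,
        MolecularProfile.START_LOSS,
        MolecularProfile.STRUCTURAL,
        MolecularProfile.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class PrioritizationConfig:
    maf_causal_max: float = 0.01
    maf_vus_max: float = 0.01
    gerp_min: float = 4.0
    splice_score_min: float = 0.6
    retained_profiles: frozenset[MolecularProfile] = DEFAULT_PROFILES
    tier1_genes: frozenset[str] = field(default_factory=frozenset)
    tier2_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("maf_causal_max", "maf_vus_max"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.splice_score_min <= 1:
            raise ValueError("splice_score_min must be in [0, 1]")


def profile_filter(
    variant: VariantRecord, config: PrioritizationConfig = PrioritizationConfig()
) -> tuple[bool, str]:
    """Keep variants with a retained molecular profile.

    Synonymous variants are kept only when a splice prediction rescues
    them (score >= ``splice_score_min``); a missing score drops them.
    """
    if variant.profile is MolecularProfile.SYNONYMOUS:
        if variant.splice_score is not None and variant.splice_score >= config.splice_score_min:
            return True, "synonymous rescued by splice prediction"
        return False, "synonymous without splice evidence"
    if variant.profile in config.retained_profiles:
        return True, f"profile {variant.profile.value} retained"
    return False, f"profile {variant.profile.value} not retained"


def frequency_filter(
    variant: VariantRecord, config: PrioritizationConfig = PrioritizationConfig()
) -> bool:
    """Keep iff the MAF is missing (never reported) or below the cutoff."""
    return variant.maf is None or variant.maf < config.maf_causal_max


def vus_retention(
    variant: VariantRecord, config: PrioritizationConfig = PrioritizationConfig()
) -> bool:
    """Retention gate for variants of unknown significance.

    A VUS stays in play only when it resembles a typical disease allele:
    (i) rare (MAF < ``maf_vus_max``, missing counts as unobserved),
    (ii) impactful at the protein level or splice-predicted, and
    (iii) well conserved (GERP > ``gerp_min``) or splice-predicted.
    """
    if variant.clinical_class is not ClinicalClass.VUS:
        raise ValueError("vus_retention applies only to VUS variants")
    rare = variant.maf is None or variant.maf < config.maf_vus_max
    splice_pred = (
        variant.splice_score is not None
        and variant.splice_score >= config.splice_score_min
    )
    impact = variant.profile is not MolecularProfile.SYNONYMOUS or splice_pred
    conserved = (variant.gerp is not None and variant.gerp > config.gerp_min) or splice_pred
    return rare and impact and conserved


def gene_tier(gene: str, config: PrioritizationConfig) -> int:
    """1 for panel genes, 2 for phenotype-database genes, 3 otherwise."""
    if gene in config.tier1_genes:
        return 1
    if gene in config.tier2_genes:
        return 2
    return 3


def prioritize_variants(
    variants: list[VariantRecord],
    config: PrioritizationConfig = PrioritizationConfig(),
) -> list[VariantRecord]:
    """Intersection of the independent filters (order-free by construction)."""
    kept = []
    for v in variants:
        if not profile_filter(v, config)[0]:
            continue
        if not frequency_filter(v, config):
            continue
        if v.clinical_class is ClinicalClass.VUS and not vus_retention(v, config):
            continue
        if v.clinical_class in (ClinicalClass.B, ClinicalClass.LB):
            continue
        kept.append(v)
    return kept


def _pair_phase(g1: GenotypeCall, g2: GenotypeCall) -> Phase:
    mutual = g1.phase_partner == g2.variant_id and g2.phase_partner == g1.variant_id
    if mutual and g1.phase == g2.phase and g1.phase in (Phase.IN_TRANS, Phase.IN_CIS):
        return g1.phase
    return Phase.UNKNOWN


def _with_phase(g: GenotypeCall, partner: str, phase: Phase) -> GenotypeCall:
    return dataclasses.replace(g, phase_partner=partner, phase=phase)


def inheritance_candidates(
    patient: PatientRecord,
    genotype_calls: list[GenotypeCall],
    variants: dict[str, VariantRecord],
    config: PrioritizationConfig = PrioritizationConfig(),
) -> list[tuple[GenotypeCall, ...]]:
    """Candidate genotype configurations compatible with the inheritance mode.

    Recessive/isolated: homozygous singletons and heterozygous pairs within
    one gene (a single het is never a candidate).  Dominant: heterozygous
    singletons.  X-linked: hemizygous singletons for males, X-chromosome
    heterozygous singletons for females.  Unknown inheritance: the union of
    all of the above.  Candidates are returned sorted by gene tier.
    """
    inh = patient.inheritance
    modes: list[Inheritance]
    if inh is Inheritance.UNKNOWN:
        modes = [Inheritance.AR, Inheritance.AD, Inheritance.XL]
    elif inh is Inheritance.ISOLATED:
        modes = [Inheritance.AR]
    else:
        modes = [inh]

    by_gene: dict[str, list[GenotypeCall]] = {}
    for g in genotype_calls:
        v = variants.get(g.variant_id)
        if v is None:
            raise KeyError(f"genotype references unknown variant {g.variant_id}")
        by_gene.setdefault(v.gene, []).append(g)

    candidates: list[tuple[GenotypeCall, ...]] = []
    seen: set[tuple[str, ...]] = set()

    def add(cand: tuple[GenotypeCall, ...]) -> None:
        key = tuple(sorted(g.variant_id for g in cand))
        if key not in seen:
            seen.add(key)
            candidates.append(cand)

    for mode in modes:
        for gene, calls in by_gene.items():
            if mode is Inheritance.AR:
                for g in calls:
                    if g.zygosity is Zygosity.HOM:
                        add((g,))
                hets = [g for g in calls if g.zygosity is Zygosity.HET]
                for g1, g2 in combinations(hets, 2):
                    phase = _pair_phase(g1, g2)
                    add(
                        (
                            _with_phase(g1, g2.variant_id, phase),
                            _with_phase(g2, g1.variant_id, phase),
                        )
                    )
            elif mode is Inheritance.AD:
                for g in calls:
                    if g.zygosity is Zygosity.HET:
                        add((g,))
            elif mode is Inheritance.XL:
                for g in calls:
                    v = variants[g.variant_id]
                    if patient.sex is Sex.MALE and g.zygosity is Zygosity.HEMI:
                        add((g,))
                    elif (
                        patient.sex is Sex.FEMALE
                        and g.zygosity is Zygosity.HET
                        and v.chrom == "X"
                    ):
                        add((g,))

    def cand_tier(cand: tuple[GenotypeCall, ...]) -> int:
        return min(gene_tier(variants[g.variant_id].gene, config) for g in cand)

    candidates.sort(key=cand_tier)
    return candidates
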