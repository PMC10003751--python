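"""Synthetic-cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes — founder recessive alleles with skewed recurrence, homozygous
causal genotypes embedded in planted runs of homozygosity, an
inheritance-mode mixture matching a clinic-based IRD cohort, biallelic
marker tracks, and per-exon depth matrices with copy-number signal — so
every stage of the pipeline is testable offline.

The generator plants ground truth first (diagnostic category, causal
genotype, ROH intervals) and emits it alongside the data; no analysis
stage may read the truth except tests.  All randomness flows through a
single integer-seeded ``numpy.random.default_rng`` stream, so a given
seed reproduces the cohort byte-for-byte on any platform.

The defaults describe the cohort the pipeline was designed around:
230 index families, inheritance mixture 48% isolated / 37% recessive /
7% dominant / 7% X-linked (remainder unascertained), 76% of index cases
diagnosable, 51% of diagnosed recessive genotypes homozygous, and a
founder-allele list whose most recurrent member is a two-exon deletion
planted 17 times (eight homozygotes).  ROH lengths are exponential with
a 5 Mb mean; markers are spaced 3 kb with a 0.2% heterozygous genotyping
error; exon depth averages 150x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    GT_AA,
    GT_AB,
    GT_BB,
    ClinicalClass,
    CoverageMatrix,
    DiagnosticStatus,
    GenotypeCall,
    Inheritance,
    MarkerTrack,
    MolecularProfile,
    PatientRecord,
    Phase,
    Sex,
    VariantKind,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "FounderAllele",
    "SimConfig",
    "CohortTruth",
    "simulate_cohort",
    "simulate_marker_track",
    "simulate_coverage",
    "CHROM_LENGTHS",
    "DEFAULT_FOUNDERS",
]

# approximate GRCh37 chromosome lengths (bp)
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}

# gene anchors (gene, chrom, position) used when placing causal variants
_AR_GENES = [
    ("EYS", "6", 65_500_000), ("ABCA4", "1", 94_500_000), ("USH2A", "1", 215_900_000),
    ("CRB1", "1", 197_200_000), ("CNGB3", "8", 87_600_000), ("RPE65", "1", 68_900_000),
    ("RAB28", "4", 13_400_000), ("DRAM2", "1", 111_660_000), ("CERKL", "2", 182_400_000),
    ("PDE6B", "4", 620_000), ("AIPL1", "17", 6_330_000), ("TULP1", "6", 35_460_000),
    ("CNGA3", "2", 98_960_000), ("MERTK", "2", 112_650_000), ("LCA5", "6", 80_190_000),
    ("RDH12", "14", 68_190_000), ("CEP290", "12", 88_440_000), ("MYO7A", "11", 76_840_000),
    ("PDE6A", "5", 149_230_000), ("SPATA7", "14", 88_850_000),
]
_AD_GENES = [
    ("RHO", "3", 129_240_000), ("PRPH2", "6", 42_660_000), ("PRPF31", "19", 54_620_000),
    ("SNRNP200", "2", 96_940_000), ("CRX", "19", 48_320_000),
]
_XL_GENES = [("RPGR", "X", 38_130_000), ("RP2", "X", 46_690_000), ("CHM", "X", 85_120_000)]

_PHENOTYPES = [
    ("retinitis_pigmentosa", 0.47), ("cone_rod_dystrophy", 0.14),
    ("leber_congenital_amaurosis", 0.10), ("usher_syndrome", 0.06),
    ("stargardt_macular_dystrophy", 0.06), ("cone_dystrophy", 0.05),
    ("chorioretinal_dystrophy", 0.04), ("syndromic_ird", 0.04),
    ("achromatopsia", 0.02), ("csnb", 0.01), ("xl_retinoschisis", 0.005),
    ("other", 0.005),
]


@dataclass(frozen=True)
class FounderAllele:
    """A recurrent allele planted at a target number of allele copies."""

    gene: str
    target_occurrences: int
    kind: VariantKind = VariantKind.SNV


#: Founder list emulating a recurrence-skewed cohort: the top allele is a
#: two-exon deletion with 17 copies (eight homozygotes + one het carrier).
DEFAULT_FOUNDERS: tuple[FounderAllele, ...] = (
    FounderAllele("EYS", 17, VariantKind.CNV_DEL),
    FounderAllele("ABCA4", 10, VariantKind.SNV),
    FounderAllele("USH2A", 8, VariantKind.SNV),
    FounderAllele("RAB28", 8, VariantKind.SNV),
    FounderAllele("CNGB3", 6, VariantKind.INDEL),
    FounderAllele("RPE65", 5, VariantKind.SNV),
    FounderAllele("CRB1", 5, VariantKind.SNV),
    FounderAllele("CERKL", 4, VariantKind.SNV),
    FounderAllele("PDE6B", 4, VariantKind.SNV),
    FounderAllele("AIPL1", 3, VariantKind.SNV),
    FounderAllele("CEP290", 6, VariantKind.SNV),
    FounderAllele("MYO7A", 5, VariantKind.SNV),
    FounderAllele("PDE6A", 4, VariantKind.SNV),
    FounderAllele("SPATA7", 4, VariantKind.INDEL),
    FounderAllele("DRAM2", 3, VariantKind.SNV),
    FounderAllele("USH2A", 3, VariantKind.SNV),
    FounderAllele("ABCA4", 3, VariantKind.SNV),
    FounderAllele("TULP1", 2, VariantKind.SNV),
    FounderAllele("CNGA3", 2, VariantKind.SNV),
    FounderAllele("MERTK", 2, VariantKind.SNV),
    FounderAllele("LCA5", 2, VariantKind.INDEL),
    FounderAllele("RDH12", 2, VariantKind.SNV),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``inheritance_mix`` fractions must sum to at most 1; any remainder is
    the fraction of probands with unascertainable inheritance.
    """

    n_index: int = 230
    inheritance_mix: dict[str, float] = field(
        default_factory=lambda: {"isolated": 0.48, "AR": 0.37, "AD": 0.07, "XL": 0.07}
    )
    founder_alleles: tuple[FounderAllele, ...] = DEFAULT_FOUNDERS
    private_allele_rate: float = 1.0  # remaining causal slots are private alleles
    diagnosed_fraction: float = 0.76
    uncertain_fraction: float = 0.08
    likely_solved_fraction: float = 0.15  # of diagnosed recessive cases
    hom_fraction: float = 0.51  # homozygous share of diagnosed recessive genotypes
    founder_het_rate: float = 0.1  # chance a founder copy travels in a het carrier
    xl_male_fraction: float = 0.8
    roh_mean_length_mb: float = 5.0
    roh_min_length_mb: float = 1.5
    background_roh_rate: float = 2.0  # Poisson mean of incidental ROHs per genome
    roh_outlier: bool = False  # plant one hom causal variant outside any ROH
    marker_spacing_bp: int = 3000
    het_error_rate: float = 0.002
    background_het_fraction: float = 0.35
    depth_mean: float = 150.0
    depth_dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_index < 0:
            raise ValueError("n_index must be >= 0")
        total = sum(self.inheritance_mix.values())
        if total > 1 + 1e-9:
            raise ValueError("inheritance_mix fractions must sum to <= 1")
        for name in (
            "private_allele_rate", "diagnosed_fraction", "uncertain_fraction",
            "likely_solved_fraction", "hom_fraction", "founder_het_rate",
            "xl_male_fraction", "het_error_rate", "background_het_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")


@dataclass
class CohortTruth:
    """Planted ground truth, emitted alongside the data.

    ``table`` has one row per index patient: expected diagnostic status,
    genotype class, causal variant ids, and whether a homozygous causal
    variant lies inside a planted ROH.  ``planted_roh`` maps patient to
    (chrom, start, end) intervals.
    """

    table: pd.DataFrame
    planted_roh: dict[str, list[tuple[str, int, int]]]

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["planted_roh"] = [
            ";".join(f"{c}:{s}-{e}" for c, s, e in self.planted_roh.get(pid, []))
            for pid in df["patient_id"]
        ]
        df.to_csv(path, sep="\t", index=False)


def _draw_inheritance(rng: np.random.Generator, config: SimConfig, n: int) -> list[Inheritance]:
    modes = list(config.inheritance_mix) + ["unknown"]
    probs = list(config.inheritance_mix.values())
    probs.append(max(0.0, 1.0 - sum(probs)))
    drawn = rng.choice(len(modes), size=n, p=np.array(probs) / sum(probs))
    return [Inheritance(modes[i]) for i in drawn]


def _variant_position(rng: np.random.Generator, gene: str) -> tuple[str, int]:
    for pool in (_AR_GENES, _AD_GENES, _XL_GENES):
        for g, chrom, anchor in pool:
            if g == gene:
                return chrom, anchor + int(rng.integers(0, 200_000))
    # unknown gene: place on a random autosome
    chrom = str(rng.integers(1, 23))
    return chrom, int(rng.integers(1_000_000, CHROM_LENGTHS[chrom] - 1_000_000))


_BASES = np.array(list("ACGT"))


def _make_variant(
    rng: np.random.Generator,
    vid: str,
    gene: str,
    kind: VariantKind,
    clinical_class: ClinicalClass,
) -> VariantRecord:
    chrom, pos = _variant_position(rng, gene)
    if kind is VariantKind.SNV:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        start = end = pos
        profile = MolecularProfile(
            rng.choice(["missense", "nonsense", "splice_region", "missense"])
        )
    elif kind is VariantKind.INDEL:
        ref = "".join(rng.choice(_BASES, size=4))
        alt = ref[0]
        start, end = pos, pos + 3
        profile = MolecularProfile.FRAMESHIFT
    else:  # CNV
        ref = alt = ""
        start, end = pos, pos + int(rng.integers(5_000, 150_000))
        profile = MolecularProfile.STRUCTURAL
    return VariantRecord(
        variant_id=vid,
        gene=gene,
        chrom=chrom,
        start=start,
        end=int(end),
        ref=str(ref),
        alt=str(alt),
        kind=kind,
        profile=profile,
        maf=None if rng.random() < 0.5 else float(rng.uniform(0, 0.005)),
        gerp=float(rng.uniform(4.2, 6.0)),
        splice_score=None,
        clinical_class=clinical_class,
        novel=bool(rng.random() < 0.2),
    )


def simulate_cohort(
    config: SimConfig = SimConfig(),
) -> tuple[list[PatientRecord], list[VariantRecord], list[GenotypeCall], CohortTruth]:
    """Generate a full synthetic cohort with its planted truth.

    Founder alleles are planted at exactly ``target_occurrences`` allele
    copies (h homozygotes and r heterozygous carriers, 2h + r = target),
    consuming diagnosed-recessive patient slots; leftover slots receive
    private alleles.  Dominant patients get one heterozygous P/LP,
    X-linked males one hemizygous P/LP, X-linked females one
    heterozygous P/LP on X.  Configured fractions of patients receive
    genotypes that must classify as uncertain (VUS configurations) or
    unsolved (a single het P/LP in a recessive gene, or nothing).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_index
    for f in config.founder_alleles:
        if f.target_occurrences > 2 * n:
            raise ValueError(
                f"founder allele in {f.gene} needs {f.target_occurrences} copies "
                f"but the cohort holds at most {2 * n}"
            )

    inheritances = _draw_inheritance(rng, config, n)
    patients: list[PatientRecord] = []
    for i in range(n):
        inh = inheritances[i]
        if inh is Inheritance.XL:
            sex = Sex.MALE if rng.random() < config.xl_male_fraction else Sex.FEMALE
        else:
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        pheno = rng.choice(
            [p for p, _w in _PHENOTYPES],
            p=np.array([w for _p, w in _PHENOTYPES]) / sum(w for _p, w in _PHENOTYPES),
        )
        birth = int(np.clip(rng.normal(1977, 15), 1935, 2015))
        patients.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                sex=sex,
                inheritance=inh,
                phenotype_class=str(pheno),
                birth_year=birth,
            )
        )

    # draw diagnostic category per patient
    cat = rng.random(n)
    category: list[DiagnosticStatus] = []
    for i, p in enumerate(patients):
        if cat[i] < config.diagnosed_fraction:
            if p.inheritance.recessive_context and rng.random() < config.likely_solved_fraction:
                category.append(DiagnosticStatus.LIKELY_SOLVED)
            else:
                category.append(DiagnosticStatus.SOLVED)
        elif cat[i] < config.diagnosed_fraction + config.uncertain_fraction:
            category.append(DiagnosticStatus.UNCERTAIN)
        else:
            category.append(DiagnosticStatus.UNSOLVED)

    # recessive diagnosed patients are the substrate for founder planting
    rec_solved = [
        i for i, p in enumerate(patients)
        if p.inheritance.recessive_context and category[i] is DiagnosticStatus.SOLVED
    ]
    rng.shuffle(rec_solved)
    # the homozygous share is defined over ALL diagnosed recessive cases;
    # likely-solved configurations are two-variant by construction, so the
    # homozygotes all come out of the solved pool
    n_rec_likely = sum(
        1 for i, p in enumerate(patients)
        if p.inheritance.recessive_context
        and category[i] is DiagnosticStatus.LIKELY_SOLVED
    )
    n_hom_target = min(
        len(rec_solved),
        int(round(config.hom_fraction * (len(rec_solved) + n_rec_likely))),
    )
    hom_slots = rec_solved[:n_hom_target]
    comphet_slots = rec_solved[n_hom_target:]

    variants: list[VariantRecord] = []
    genotypes: list[GenotypeCall] = []
    truth_rows: list[dict] = []
    causal: dict[int, list[str]] = {i: [] for i in range(n)}
    gclass: dict[int, str] = {}
    vid_counter = 0

    def new_vid() -> str:
        nonlocal vid_counter
        vid_counter += 1
        return f"V{vid_counter:05d}"

    hom_queue = list(hom_slots)
    comphet_queue = list(comphet_slots)

    # founder alleles first: h homozygotes + r het carriers, 2h + r = target
    for founder in config.founder_alleles:
        t = founder.target_occurrences
        r = int(rng.binomial(t, config.founder_het_rate))
        if (t - r) % 2:
            r += 1 if r < t else -1
        h = (t - r) // 2
        if h > len(hom_queue) or r > len(comphet_queue):
            raise ValueError(
                f"founder allele in {founder.gene} needs {h} homozygous and {r} "
                "het slots; not enough diagnosed recessive patients in this cohort"
            )
        fv = _make_variant(
            rng, new_vid(), founder.gene, founder.kind, ClinicalClass.P
        )
        variants.append(fv)
        for _ in range(h):
            i = hom_queue.pop()
            genotypes.append(
                GenotypeCall(patients[i].patient_id, fv.variant_id, Zygosity.HOM)
            )
            causal[i].append(fv.variant_id)
            gclass[i] = "AR_hom"
        for _ in range(r):
            i = comphet_queue.pop()
            second = _make_variant(
                rng, new_vid(), founder.gene, VariantKind.SNV, ClinicalClass.P
            )
            variants.append(second)
            genotypes.append(
                GenotypeCall(
                    patients[i].patient_id, fv.variant_id, Zygosity.HET,
                    phase_partner=second.variant_id, phase=Phase.IN_TRANS,
                )
            )
            genotypes.append(
                GenotypeCall(
                    patients[i].patient_id, second.variant_id, Zygosity.HET,
                    phase_partner=fv.variant_id, phase=Phase.IN_TRANS,
                )
            )
            causal[i] += [fv.variant_id, second.variant_id]
            gclass[i] = "AR_comp_het"

    # remaining diagnosed patients get private alleles
    ar_gene_names = [g for g, _c, _p in _AR_GENES]
    for i in hom_queue:
        gene = str(rng.choice(ar_gene_names))
        v = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.P)
        variants.append(v)
        genotypes.append(GenotypeCall(patients[i].patient_id, v.variant_id, Zygosity.HOM))
        causal[i].append(v.variant_id)
        gclass[i] = "AR_hom"
    for i in comphet_queue:
        gene = str(rng.choice(ar_gene_names))
        v1 = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.P)
        v2 = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.LP)
        variants += [v1, v2]
        genotypes.append(
            GenotypeCall(patients[i].patient_id, v1.variant_id, Zygosity.HET,
                         phase_partner=v2.variant_id, phase=Phase.IN_TRANS)
        )
        genotypes.append(
            GenotypeCall(patients[i].patient_id, v2.variant_id, Zygosity.HET,
                         phase_partner=v1.variant_id, phase=Phase.IN_TRANS)
        )
        causal[i] += [v1.variant_id, v2.variant_id]
        gclass[i] = "AR_comp_het"

    for i, p in enumerate(patients):
        status = category[i]
        if p.inheritance.recessive_context:
            if status is DiagnosticStatus.LIKELY_SOLVED:
                gene = str(rng.choice(ar_gene_names))
                cls2 = ClinicalClass.VUS if rng.random() < 0.5 else ClinicalClass.P
                v1 = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.P)
                v2 = _make_variant(rng, new_vid(), gene, VariantKind.SNV, cls2)
                phase = Phase.IN_TRANS if cls2 is ClinicalClass.VUS else Phase.UNKNOWN
                variants += [v1, v2]
                for a, b in ((v1, v2), (v2, v1)):
                    genotypes.append(
                        GenotypeCall(p.patient_id, a.variant_id, Zygosity.HET,
                                     phase_partner=b.variant_id, phase=phase)
                    )
                causal[i] += [v1.variant_id, v2.variant_id]
                gclass[i] = "AR_comp_het"
            elif status is DiagnosticStatus.UNCERTAIN:
                gene = str(rng.choice(ar_gene_names))
                v = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.VUS)
                variants.append(v)
                genotypes.append(GenotypeCall(p.patient_id, v.variant_id, Zygosity.HOM))
                causal[i].append(v.variant_id)
            elif status is DiagnosticStatus.UNSOLVED and rng.random() < 0.5:
                gene = str(rng.choice(ar_gene_names))
                v = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.P)
                variants.append(v)
                genotypes.append(GenotypeCall(p.patient_id, v.variant_id, Zygosity.HET))
        elif p.inheritance is Inheritance.AD:
            if status in (DiagnosticStatus.SOLVED, DiagnosticStatus.LIKELY_SOLVED):
                category[i] = status = DiagnosticStatus.SOLVED
                gene = str(rng.choice([g for g, _c, _p in _AD_GENES]))
                v = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.LP)
                variants.append(v)
                genotypes.append(GenotypeCall(p.patient_id, v.variant_id, Zygosity.HET))
                causal[i].append(v.variant_id)
                gclass[i] = "AD_het"
            elif status is DiagnosticStatus.UNCERTAIN:
                gene = str(rng.choice([g for g, _c, _p in _AD_GENES]))
                v = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.VUS)
                variants.append(v)
                genotypes.append(GenotypeCall(p.patient_id, v.variant_id, Zygosity.HET))
                causal[i].append(v.variant_id)
        elif p.inheritance is Inheritance.XL:
            if status in (DiagnosticStatus.SOLVED, DiagnosticStatus.LIKELY_SOLVED):
                category[i] = status = DiagnosticStatus.SOLVED
                gene = str(rng.choice([g for g, _c, _p in _XL_GENES]))
                v = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.P)
                variants.append(v)
                zyg = Zygosity.HEMI if p.sex is Sex.MALE else Zygosity.HET
                genotypes.append(GenotypeCall(p.patient_id, v.variant_id, zyg))
                causal[i].append(v.variant_id)
                gclass[i] = "XL_hemi" if p.sex is Sex.MALE else "XL_het_female"
            elif status is DiagnosticStatus.UNCERTAIN:
                gene = str(rng.choice([g for g, _c, _p in _XL_GENES]))
                v = _make_variant(rng, new_vid(), gene, VariantKind.SNV, ClinicalClass.VUS)
                variants.append(v)
                zyg = Zygosity.HEMI if p.sex is Sex.MALE else Zygosity.HET
                genotypes.append(GenotypeCall(p.patient_id, v.variant_id, zyg))
                causal[i].append(v.variant_id)

    # plant ROHs: every homozygous causal genotype sits inside an interval
    # (except one flagged outlier when configured); everyone gets
    # incidental background ROHs
    vmap = {v.variant_id: v for v in variants}
    planted_roh: dict[str, list[tuple[str, int, int]]] = {}
    causal_in_roh: dict[int, bool] = {}
    outlier_pending = config.roh_outlier
    for i, p in enumerate(patients):
        intervals: list[tuple[str, int, int]] = []
        hom_vids = [
            g.variant_id
            for g in genotypes
            if g.patient_id == p.patient_id and g.zygosity is Zygosity.HOM
        ]
        for vid in hom_vids:
            v = vmap[vid]
            if outlier_pending and gclass.get(i) == "AR_hom":
                causal_in_roh[i] = False
                outlier_pending = False
                continue
            length = _roh_length(rng, config)
            offset = int(rng.uniform(0.15, 0.85) * length)
            start = max(1, v.start - offset)
            end = min(CHROM_LENGTHS.get(v.chrom, 150_000_000), start + length - 1)
            intervals.append((v.chrom, start, end))
            causal_in_roh[i] = True
        for _ in range(int(rng.poisson(config.background_roh_rate))):
            chrom = str(rng.integers(1, 23))
            length = _roh_length(rng, config)
            start = int(rng.integers(1, CHROM_LENGTHS[chrom] - length))
            intervals.append((chrom, start, start + length - 1))
        planted_roh[p.patient_id] = _drop_overlaps(intervals)

    for i, p in enumerate(patients):
        truth_rows.append(
            {
                "patient_id": p.patient_id,
                "expected_status": category[i].value,
                "genotype_class": gclass.get(i, ""),
                "causal_variants": ";".join(causal[i]),
                "causal_in_roh": causal_in_roh.get(i, None),
            }
        )
    truth = CohortTruth(table=pd.DataFrame(truth_rows), planted_roh=planted_roh)
    return patients, variants, genotypes, truth


def _roh_length(rng: np.random.Generator, config: SimConfig) -> int:
    """Exponential ROH length with a floor (sub-Mb blocks are not the
    autozygosity signal this pipeline studies)."""
    mb = config.roh_min_length_mb + rng.exponential(
        max(config.roh_mean_length_mb - config.roh_min_length_mb, 0.1)
    )
    return int(mb * 1e6)


def _drop_overlaps(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    kept: list[tuple[str, int, int]] = []
    for iv in sorted(intervals):
        if any(c == iv[0] and s <= iv[2] and e >= iv[1] for c, s, e in kept):
            continue
        kept.append(iv)
    return kept


def simulate_marker_track(
    patient_id: str,
    chrom: str,
    planted_roh: list[tuple[int, int]],
    config: SimConfig = SimConfig(),
    *,
    seed: int | None = None,
    chrom_length: int | None = None,
) -> MarkerTrack:
    """Biallelic marker track with planted homozygous intervals.

    Markers sit every ``marker_spacing_bp`` along the chromosome.  Inside
    a planted interval genotypes are homozygous apart from
    Bernoulli(``het_error_rate``) heterozygous miscalls; outside,
    ``background_het_fraction`` of markers are heterozygous.  Planted
    intervals must not overlap.
    """
    length = chrom_length or CHROM_LENGTHS.get(chrom)
    if length is None:
        raise ValueError(f"unknown chromosome {chrom!r}; pass chrom_length")
    ivals = sorted(planted_roh)
    for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
        if s2 <= e1:
            raise ValueError("planted ROH intervals overlap")
    for s, e in ivals:
        if s < 1 or e > length:
            raise ValueError(f"planted interval ({s}, {e}) outside chromosome")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    positions = np.arange(1, length + 1, config.marker_spacing_bp, dtype=np.int64)
    n = positions.size
    hom = np.where(rng.random(n) < 0.5, GT_AA, GT_BB).astype(np.int8)
    genotypes = np.where(
        rng.random(n) < config.background_het_fraction, GT_AB, hom
    ).astype(np.int8)
    inside = np.zeros(n, dtype=bool)
    for s, e in ivals:
        inside |= (positions >= s) & (positions <= e)
    genotypes[inside] = hom[inside]
    flips = inside & (rng.random(n) < config.het_error_rate)
    genotypes[flips] = GT_AB
    return MarkerTrack(
        patient_id=patient_id, chrom=chrom, positions=positions, genotypes=genotypes
    )


def simulate_coverage(
    gene_model: list[tuple[str, int, str, int, int]],
    samples: list[str],
    carriers: dict[str, tuple[int, tuple[int, int]]],
    config: SimConfig = SimConfig(),
    *,
    seed: int | None = None,
) -> CoverageMatrix:
    """Per-exon depth matrix with copy-number signal.

    ``carriers`` maps patient -> (copy_number, (first_exon, last_exon));
    copy number 2 is diploid, 1 a het deletion, 0 a hom deletion, 3 a
    gain.  Depth is negative-binomial around
    ``depth_mean * copy_number / 2`` (gamma-mixed Poisson with dispersion
    ``depth_dispersion``), modulated by a per-exon capture-efficiency
    factor shared across samples and a per-sample library-size factor —
    both of which downstream normalization must remove.
    """
    if config.depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")
    for pid, (cn, span) in carriers.items():
        if pid not in samples:
            raise ValueError(f"carrier {pid} not among samples")
        if cn not in (0, 1, 2, 3):
            raise ValueError(f"copy_number must be in 0..3, got {cn}")
        exon_numbers = [e[1] for e in gene_model]
        if span[0] not in exon_numbers or span[1] not in exon_numbers:
            raise ValueError(f"carrier {pid} exon span {span} outside gene model")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_exons, n_samples = len(gene_model), len(samples)
    capture = rng.lognormal(mean=0.0, sigma=0.15, size=n_exons)
    libsize = rng.lognormal(mean=0.0, sigma=0.15, size=n_samples)
    cn = np.full((n_exons, n_samples), 2.0)
    for j, pid in enumerate(samples):
        if pid in carriers:
            c, (lo, hi) = carriers[pid]
            for i, (_g, num, _c, _s, _e) in enumerate(gene_model):
                if lo <= num <= hi:
                    cn[i, j] = c
    mean = config.depth_mean * (cn / 2.0) * capture[:, None] * libsize[None, :]
    alpha = max(config.depth_dispersion, 1e-9)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.maximum(mean, 1e-12))
    depth = rng.poisson(lam).astype(float)
    depth[mean == 0] = 0.0
    return CoverageMatrix(exons=list(gene_model), samples=list(samples), depth=depth)
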