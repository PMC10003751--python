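"""Cohort landscape statistics: occurrences, recurrence, prevalence, trends."""

import numpy as np
import pandas as pd
import pytest

from irdscape.diagnose import AssortmentEntry, GenotypeAssortment, diagnose_cohort
from irdscape.landscape import (
    GenotypeClass,
    allele_occurrences,
    birth_cohort_trend,
    gene_prevalence,
    genotype_class,
    recurrence_spectrum,
    variant_class_counts,
    zygosity_breakdown,
)
from irdscape.model import (
    ClinicalClass,
    GenotypeCall,
    PatientRecord,
    VariantKind,
    VariantRecord,
    Zygosity,
)
from irdscape.simulate import FounderAllele, SimConfig, simulate_cohort


def _variant(vid, gene="EYS", kind=VariantKind.SNV):
    return VariantRecord(
        variant_id=vid, gene=gene, chrom="6", start=100, end=100,
        ref="A", alt="G", kind=kind, clinical_class=ClinicalClass.P,
    )


class TestAlleleOccurrences:
    def test_eight_homs_one_het_count_17(self):
        calls = [GenotypeCall(f"p{i}", "v1", Zygosity.HOM) for i in range(8)]
        calls.append(GenotypeCall("p8", "v1", Zygosity.HET))
        assert allele_occurrences("v1", calls) == 17

    def test_single_het_counts_one(self):
        assert allele_occurrences("v1", [GenotypeCall("p", "v1", Zygosity.HET)]) == 1

    def test_hemizygote_counts_one(self):
        assert allele_occurrences("v1", [GenotypeCall("p", "v1", Zygosity.HEMI)]) == 1

    def test_no_carriers_counts_zero(self):
        assert allele_occurrences("v1", []) == 0


class TestRecurrenceSpectrum:
    CALLS = [
        GenotypeCall("p1", "a", Zygosity.HET),
        GenotypeCall("p2", "b", Zygosity.HET),
        GenotypeCall("p3", "c", Zygosity.HOM),
    ]
    VARIANTS = [_variant("a"), _variant("b"), _variant("c")]

    def test_distinct_variant_denominator(self):
        spec = recurrence_spectrum(self.VARIANTS, self.CALLS, "distinct_variants")
        assert spec == pytest.approx({"once": 2 / 3, "twice": 1 / 3, "three_plus": 0})

    def test_allele_denominator(self):
        spec = recurrence_spectrum(self.VARIANTS, self.CALLS, "alleles")
        assert spec == pytest.approx({"once": 2 / 4, "twice": 2 / 4, "three_plus": 0})

    def test_denominators_agree_when_counts_equal(self):
        calls = [
            GenotypeCall("p1", "a", Zygosity.HET),
            GenotypeCall("p2", "b", Zygosity.HET),
        ]
        variants = [_variant("a"), _variant("b")]
        assert recurrence_spectrum(variants, calls, "distinct_variants") == (
            recurrence_spectrum(variants, calls, "alleles")
        )

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            recurrence_spectrum([], [], "alleles")

    def test_planted_spectrum_recovered_at_scale(self):
        """A founder-heavy generator config reproduces its recurrence skew
        within a few percent at n=500."""
        # 296 founder alleles, all in the >=3 bin, over ~700 causative
        # alleles at n=500: a planted three-plus share of ~0.42
        founders = tuple(
            FounderAllele(g, t)
            for g, t in [
                ("EYS", 64), ("ABCA4", 38), ("USH2A", 30), ("RAB28", 30),
                ("CNGB3", 22), ("RPE65", 18), ("CRB1", 18), ("CERKL", 14),
                ("PDE6B", 14), ("AIPL1", 10), ("TULP1", 8), ("CNGA3", 8),
                ("MERTK", 8), ("LCA5", 8), ("RDH12", 6),
            ]
        )
        config = SimConfig(n_index=500, founder_alleles=founders, seed=17)
        patients, variants, genotypes, truth = simulate_cohort(config)
        diagnosed = set(
            truth.table.loc[
                truth.table["expected_status"].isin(["solved", "likely_solved"]),
                "patient_id",
            ]
        )
        causal = {
            (row["patient_id"], vid)
            for _i, row in truth.table.iterrows()
            for vid in str(row["causal_variants"]).split(";")
            if vid and row["patient_id"] in diagnosed
        }
        calls = [g for g in genotypes if (g.patient_id, g.variant_id) in causal]
        spec = recurrence_spectrum(variants, calls, "alleles")
        total_alleles = sum(2 if g.zygosity is Zygosity.HOM else 1 for g in calls)
        planted_three_plus = 296  # every founder target is >= 3
        assert spec["three_plus"] == pytest.approx(
            planted_three_plus / total_alleles, abs=1e-9
        )
        assert abs(spec["three_plus"] - 0.42) <= 0.03
        assert abs(sum(spec.values()) - 1) < 1e-9


class TestGenePrevalence:
    def test_ten_of_hundred(self):
        patients = [
            PatientRecord(f"p{i}", "male", "AR", status="solved") for i in range(100)
        ]
        causal = {f"p{i}": ("EYS" if i < 10 else f"G{i}") for i in range(100)}
        table = gene_prevalence(patients, causal)
        row = table[table["gene"] == "EYS"].iloc[0]
        assert row["n_index_cases"] == 10 and row["percent"] == pytest.approx(10.0)

    def test_empty_diagnosed_set(self):
        patients = [PatientRecord("p", "male", "AR", status="unsolved")]
        assert gene_prevalence(patients, {}).empty

    def test_small_genes_groupable(self):
        patients = [
            PatientRecord(f"p{i}", "male", "AR", status="solved") for i in range(6)
        ]
        causal = {"p0": "A", "p1": "A", "p2": "A", "p3": "B", "p4": "C", "p5": "C"}
        table = gene_prevalence(patients, causal, group_small=True, small_max=2)
        assert set(table["gene"]) == {"A", "other"}
        assert int(table.loc[table["gene"] == "other", "n_index_cases"].iloc[0]) == 3


def _assort(inh, entries, sex="male"):
    return GenotypeAssortment(inh, sex, entries)


class TestZygosityBreakdown:
    def test_all_hom(self):
        patients = [
            PatientRecord(f"p{i}", "male", "AR", status="solved") for i in range(3)
        ]
        assorts = {
            p.patient_id: _assort(
                "AR", (AssortmentEntry(ClinicalClass.P, Zygosity.HOM),)
            )
            for p in patients
        }
        frac = zygosity_breakdown(patients, assorts)
        assert frac[GenotypeClass.AR_HOM] == 1.0

    def test_one_patient_each_class(self):
        specs = [
            ("AR", (AssortmentEntry(ClinicalClass.P, Zygosity.HOM),), "male"),
            (
                "AR",
                (
                    AssortmentEntry(ClinicalClass.P, Zygosity.HET, "in_trans"),
                    AssortmentEntry(ClinicalClass.P, Zygosity.HET, "in_trans"),
                ),
                "male",
            ),
            ("AD", (AssortmentEntry(ClinicalClass.P, Zygosity.HET),), "male"),
            ("XL", (AssortmentEntry(ClinicalClass.P, Zygosity.HEMI),), "male"),
        ]
        patients, assorts = [], {}
        for i, (inh, entries, sex) in enumerate(specs):
            p = PatientRecord(f"p{i}", sex, inh, status="solved")
            patients.append(p)
            assorts[p.patient_id] = _assort(inh, entries, sex)
        frac = zygosity_breakdown(patients, assorts)
        for cls in (
            GenotypeClass.AR_HOM, GenotypeClass.AR_COMP_HET,
            GenotypeClass.AD_HET, GenotypeClass.XL_HEMI,
        ):
            assert frac[cls] == 0.25

    def test_unclassifiable_genotype_is_error(self):
        p = PatientRecord("p0", "male", "AD", status="solved")
        bad = _assort("AD", (AssortmentEntry(ClinicalClass.P, Zygosity.HOM),))
        with pytest.raises(ValueError, match="p0"):
            zygosity_breakdown([p], {"p0": bad})

    def test_planted_hom_fraction_recovered_at_scale(self):
        """The configured 51% homozygous share of diagnosed recessive
        genotypes is recovered within ±3% at n=1000."""
        config = SimConfig(n_index=1000, seed=23)
        patients, variants, genotypes, _truth = simulate_cohort(config)
        classified, assorts = diagnose_cohort(patients, variants, genotypes)
        frac = zygosity_breakdown(
            classified, {k: v for k, v in assorts.items() if v is not None}
        )
        rec = frac[GenotypeClass.AR_HOM] + frac[GenotypeClass.AR_COMP_HET]
        assert abs(frac[GenotypeClass.AR_HOM] / rec - 0.51) <= 0.03


class TestVariantClassCounts:
    def test_conservation_of_counts(self, small_cohort):
        _config, (_p, variants, genotypes, _t) = small_cohort
        counts = variant_class_counts(variants, genotypes)
        total_distinct = sum(d for d, _o in counts.values())
        total_occ = sum(o for _d, o in counts.values())
        carried = {
            v.variant_id: allele_occurrences(v.variant_id, genotypes)
            for v in variants
        }
        carried = {k: n for k, n in carried.items() if n > 0}
        assert total_distinct == len(carried)
        assert total_occ == sum(carried.values())


class TestBirthCohortTrend:
    def test_single_decade(self):
        patients = [
            PatientRecord(f"p{i}", "male", "AR", birth_year=1971 + i) for i in range(3)
        ]
        table = birth_cohort_trend(patients, {f"p{i}": 10.0 for i in range(3)})
        assert list(table["decade"]) == [1970]
        assert table["median_autozygosity_mb"].iloc[0] == 10.0

    def test_planted_decreasing_trend_recovered(self):
        rng = np.random.default_rng(0)
        patients, totals = [], {}
        for i in range(300):
            year = int(rng.integers(1940, 2000))
            pid = f"p{i}"
            patients.append(PatientRecord(pid, "male", "AR", birth_year=year))
            # autozygosity shrinking by 2 Mb per decade plus noise
            totals[pid] = 120.0 - 0.2 * (year - 1940) + rng.normal(0, 1)
        table = birth_cohort_trend(patients, totals)
        medians = table["median_autozygosity_mb"].to_numpy()
        assert np.all(np.diff(medians) < 0)

    def test_all_missing_years_warns_and_returns_empty(self):
        patients = [PatientRecord("p", "male", "AR", birth_year=None)]
        with pytest.warns(UserWarning):
            table = birth_cohort_trend(patients, {})
        assert table.empty
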