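"""Readers and writers for the pipeline's file formats.

Formats
-------
``patients.tsv``   patient_id, sex, inheritance, phenotype, birth_year
``variants.tsv``   one row per distinct variant with annotations
``genotypes.tsv``  patient_id, variant_id, zygosity, phase_partner, phase
``markers.tsv``    patient_id, chrom, pos, gt
``coverage.tsv``   gene, exon, chrom, start, end, then one column per sample
``roh.bed``        BED4+2 (chrom, 0-based start, half-open end, patient,
                   n_markers, n_het)
``cohort.vcf``     VCF v4.2 subset; CNVs as symbolic <DEL>/<DUP> with END

Missing annotation values are encoded as ``.``.  Internally every interval
is 1-based inclusive; BED conversion happens here and only here.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .model import (
    GT_CODES,
    GT_LABELS,
    ClinicalClass,
    CoverageMatrix,
    DiagnosticStatus,
    GenotypeCall,
    Inheritance,
    MarkerTrack,
    MolecularProfile,
    PatientRecord,
    Phase,
    RohSegment,
    Sex,
    VariantKind,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_patients",
    "write_patients",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "write_vcf",
    "read_marker_tracks",
    "write_marker_tracks",
    "read_coverage",
    "write_coverage",
    "read_roh_bed",
    "write_roh_bed",
]

MISSING = "."


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    if isinstance(value, float):
        return repr(value)  # shortest representation that round-trips
    return str(value)


def _parse_float(token: str) -> float | None:
    return None if token == MISSING else float(token)


def _parse_int(token: str) -> int | None:
    return None if token == MISSING else int(token)


class FormatError(ValueError):
    """A malformed line, reported with file and line number."""


def _rows(path: Path, expected_header: list[str], min_cols: int | None = None):
    """Yield (lineno, fields) for a headered TSV, validating column counts."""
    n = min_cols if min_cols is not None else len(expected_header)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header[: len(expected_header)] != expected_header:
            raise FormatError(
                f"{path}:1: expected header starting "
                f"{expected_header}, got {header}"
            )
        for lineno, fields in enumerate(reader, start=2):
            if not fields:
                continue
            if len(fields) < n:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {n} fields, got {len(fields)}"
                )
            yield lineno, fields


# ---------------------------------------------------------------------------
# patients.tsv

PATIENT_COLS = ["patient_id", "sex", "inheritance", "phenotype", "birth_year"]


def read_patients(path: str | Path) -> list[PatientRecord]:
    path = Path(path)
    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for lineno, f in _rows(path, PATIENT_COLS, min_cols=5):
        try:
            rec = PatientRecord(
                patient_id=f[0],
                sex=Sex(f[1]),
                inheritance=Inheritance(f[2]),
                phenotype_class=f[3],
                birth_year=_parse_int(f[4]),
                status=DiagnosticStatus(f[5]) if len(f) > 5 and f[5] != MISSING else None,
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if rec.patient_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate patient_id {rec.patient_id}")
        seen.add(rec.patient_id)
        patients.append(rec)
    return patients


def write_patients(patients: list[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PATIENT_COLS + ["status"])
        for p in patients:
            w.writerow(
                [
                    p.patient_id,
                    p.sex.value,
                    p.inheritance.value,
                    p.phenotype_class,
                    _fmt(p.birth_year),
                    p.status.value if p.status else MISSING,
                ]
            )


# ---------------------------------------------------------------------------
# variants.tsv

VARIANT_COLS = [
    "variant_id",
    "gene",
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "kind",
    "profile",
    "maf",
    "gerp",
    "splice_score",
    "clinical_class",
    "novel",
]


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    path = Path(path)
    out: list[VariantRecord] = []
    seen: set[str] = set()
    for lineno, f in _rows(path, VARIANT_COLS):
        try:
            rec = VariantRecord(
                variant_id=f[0],
                gene=f[1],
                chrom=f[2],
                start=int(f[3]),
                end=int(f[4]),
                ref="" if f[5] == MISSING else f[5],
                alt="" if f[6] == MISSING else f[6],
                kind=VariantKind(f[7]),
                profile=MolecularProfile(f[8]),
                maf=_parse_float(f[9]),
                gerp=_parse_float(f[10]),
                splice_score=_parse_float(f[11]),
                clinical_class=ClinicalClass(f[12]),
                novel=f[13] == "true",
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if rec.variant_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate variant_id {rec.variant_id}")
        seen.add(rec.variant_id)
        out.append(rec)
    return out


def write_variants_tsv(variants: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLS)
        for v in variants:
            w.writerow(
                [
                    v.variant_id,
                    v.gene,
                    v.chrom,
                    v.start,
                    v.end,
                    v.ref or MISSING,
                    v.alt or MISSING,
                    v.kind.value,
                    v.profile.value,
                    _fmt(v.maf),
                    _fmt(v.gerp),
                    _fmt(v.splice_score),
                    v.clinical_class.value,
                    "true" if v.novel else "false",
                ]
            )


# ---------------------------------------------------------------------------
# genotypes.tsv

GENOTYPE_COLS = ["patient_id", "variant_id", "zygosity", "phase_partner", "phase"]


def read_genotypes(path: str | Path) -> list[GenotypeCall]:
    path = Path(path)
    out: list[GenotypeCall] = []
    for lineno, f in _rows(path, GENOTYPE_COLS):
        try:
            out.append(
                GenotypeCall(
                    patient_id=f[0],
                    variant_id=f[1],
                    zygosity=Zygosity(f[2]),
                    phase_partner=None if f[3] == MISSING else f[3],
                    phase=Phase(f[4]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_genotypes(genotypes: list[GenotypeCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENOTYPE_COLS)
        for g in genotypes:
            w.writerow(
                [
                    g.patient_id,
                    g.variant_id,
                    g.zygosity.value,
                    g.phase_partner or MISSING,
                    g.phase.value,
                ]
            )


# ---------------------------------------------------------------------------
# cohort-level read/write

def read_cohort(
    directory: str | Path | None = None,
    *,
    patients: str | Path | None = None,
    variants: str | Path | None = None,
    genotypes: str | Path | None = None,
) -> tuple[list[PatientRecord], list[VariantRecord], list[GenotypeCall]]:
    """Read a cohort from a directory (or explicit paths) and cross-check it.

    A genotype referencing an unknown ``variant_id`` or ``patient_id`` is an
    error, as is a duplicate patient or variant identifier.
    """
    if directory is not None:
        d = Path(directory)
        patients = patients or d / "patients.tsv"
        genotypes = genotypes or d / "genotypes.tsv"
        if variants is None:
            vcf = d / "cohort.vcf"
            variants = vcf if vcf.exists() else d / "variants.tsv"
    if patients is None or variants is None or genotypes is None:
        raise ValueError("need a directory or explicit patients/variants/genotypes paths")

    pats = read_patients(patients)
    variants = Path(variants)
    if variants.suffix == ".vcf":
        vars_, calls_from_vcf = read_vcf(variants)
        calls = calls_from_vcf if Path(genotypes).exists() is False else read_genotypes(genotypes)
    else:
        vars_ = read_variants_tsv(variants)
        calls = read_genotypes(genotypes)

    known_v = {v.variant_id for v in vars_}
    known_p = {p.patient_id for p in pats}
    for g in calls:
        if g.variant_id not in known_v:
            raise FormatError(
                f"genotype for {g.patient_id} references unknown variant {g.variant_id}"
            )
        if g.patient_id not in known_p:
            raise FormatError(
                f"genotype references unknown patient {g.patient_id}"
            )
    return pats, vars_, calls


def write_cohort(
    patients: list[PatientRecord],
    variants: list[VariantRecord],
    genotypes: list[GenotypeCall],
    directory: str | Path,
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_patients(patients, d / "patients.tsv")
    write_variants_tsv(variants, d / "variants.tsv")
    write_genotypes(genotypes, d / "genotypes.tsv")


# ---------------------------------------------------------------------------
# VCF v4.2 subset

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind">
##INFO=<ID=PROFILE,Number=1,Type=String,Description="Molecular profile">
##INFO=<ID=MAF,Number=1,Type=String,Description="Minor allele frequency">
##INFO=<ID=GERP,Number=1,Type=String,Description="GERP conservation score">
##INFO=<ID=ADA,Number=1,Type=String,Description="Splice prediction score">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Clinical class">
##INFO=<ID=NOVEL,Number=0,Type=Flag,Description="Not previously reported">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PVID,Number=1,Type=String,Description="Phase partner variant id">
##FORMAT=<ID=PHR,Number=1,Type=String,Description="Phase relative to partner">
"""


def _chrom_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, chrom)


def write_vcf(
    variants: list[VariantRecord],
    genotypes: list[GenotypeCall],
    path: str | Path,
) -> None:
    """Write the cohort as a VCF v4.2 subset with symbolic CNV records."""
    samples = sorted({g.patient_id for g in genotypes})
    by_variant: dict[str, dict[str, GenotypeCall]] = {}
    for g in genotypes:
        by_variant.setdefault(g.variant_id, {})[g.patient_id] = g

    try:
        ordered = sorted(variants, key=lambda v: (_chrom_key(v.chrom), v.start, v.variant_id))
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unsortable variant records: {exc}") from exc

    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        seen_chroms: list[str] = []
        for v in ordered:
            if v.chrom not in seen_chroms:
                seen_chroms.append(v.chrom)
        for chrom in seen_chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + samples) + "\n")
        for v in ordered:
            symbolic = v.kind in (VariantKind.CNV_DEL, VariantKind.CNV_DUP)
            ref = v.ref if v.ref else "N"
            if symbolic:
                alt = "<DEL>" if v.kind is VariantKind.CNV_DEL else "<DUP>"
            else:
                alt = v.alt if v.alt else "N"
            info = [
                f"GENE={v.gene}",
                f"KIND={v.kind.value}",
                f"PROFILE={v.profile.value}",
            ]
            if v.maf is not None:
                info.append(f"MAF={_fmt(v.maf)}")
            if v.gerp is not None:
                info.append(f"GERP={_fmt(v.gerp)}")
            if v.splice_score is not None:
                info.append(f"ADA={_fmt(v.splice_score)}")
            info.append(f"CLASS={v.clinical_class.value}")
            if v.novel:
                info.append("NOVEL")
            info.append(f"END={v.end}")
            if symbolic:
                info.append(f"SVTYPE={'DEL' if v.kind is VariantKind.CNV_DEL else 'DUP'}")
            sample_fields = []
            for s in samples:
                g = by_variant.get(v.variant_id, {}).get(s)
                if g is None:
                    sample_fields.append("./.:.:.")
                    continue
                gt = {"het": "0/1", "hom": "1/1", "hemi": "1"}[g.zygosity.value]
                sample_fields.append(
                    f"{gt}:{g.phase_partner or MISSING}:{g.phase.value}"
                )
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.start),
                        v.variant_id,
                        ref,
                        alt,
                        MISSING,
                        "PASS",
                        ";".join(info),
                        "GT:PVID:PHR",
                    ]
                    + sample_fields
                )
                + "\n"
            )


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[GenotypeCall]]:
    """Read the VCF subset back through pysam (uncompressed text VCF)."""
    variants: list[VariantRecord] = []
    genotypes: list[GenotypeCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            kind = VariantKind(info["KIND"])
            symbolic = kind in (VariantKind.CNV_DEL, VariantKind.CNV_DUP)
            variants.append(
                VariantRecord(
                    variant_id=rec.id,
                    gene=info["GENE"],
                    chrom=rec.chrom,
                    start=rec.pos,
                    end=int(rec.stop),
                    ref="" if symbolic else rec.ref,
                    alt="" if symbolic else rec.alts[0],
                    kind=kind,
                    profile=MolecularProfile(info["PROFILE"]),
                    maf=float(info["MAF"]) if "MAF" in info else None,
                    gerp=float(info["GERP"]) if "GERP" in info else None,
                    splice_score=float(info["ADA"]) if "ADA" in info else None,
                    clinical_class=ClinicalClass(info["CLASS"]),
                    novel="NOVEL" in info,
                )
            )
            for sample, call in rec.samples.items():
                alleles = call["GT"]
                if alleles is None or all(a is None for a in alleles):
                    continue
                non_ref = [a for a in alleles if a]
                if not non_ref:
                    continue
                if len(alleles) == 1:
                    zyg = Zygosity.HEMI
                elif len(non_ref) == 2:
                    zyg = Zygosity.HOM
                else:
                    zyg = Zygosity.HET
                pp = call.get("PVID")
                ph = call.get("PHR")
                genotypes.append(
                    GenotypeCall(
                        patient_id=sample,
                        variant_id=rec.id,
                        zygosity=zyg,
                        phase_partner=None if pp in (None, MISSING) else pp,
                        phase=Phase(ph) if ph not in (None, MISSING) else Phase.NOT_APPLICABLE,
                    )
                )
    return variants, genotypes


# ---------------------------------------------------------------------------
# markers.tsv

def write_marker_tracks(tracks: list[MarkerTrack], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "patient_id": t.patient_id,
                "chrom": t.chrom,
                "pos": t.positions,
                "gt": [GT_LABELS[int(g)] for g in t.genotypes],
            }
        )
        for t in tracks
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["patient_id", "chrom", "pos", "gt"])
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_tracks(path: str | Path) -> list[MarkerTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    bad = ~df["gt"].isin(GT_CODES)
    if bad.any():
        lineno = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}:{lineno}: unknown genotype {df['gt'][bad].iloc[0]!r}")
    tracks = []
    for (pid, chrom), grp in df.groupby(["patient_id", "chrom"], sort=True):
        grp = grp.sort_values("pos")
        tracks.append(
            MarkerTrack(
                patient_id=pid,
                chrom=chrom,
                positions=grp["pos"].to_numpy(np.int64),
                genotypes=np.array([GT_CODES[g] for g in grp["gt"]], dtype=np.int8),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# coverage.tsv

def write_coverage(matrix: CoverageMatrix, path: str | Path) -> None:
    meta = pd.DataFrame(
        matrix.exons, columns=["gene", "exon", "chrom", "start", "end"]
    )
    depth = pd.DataFrame(matrix.depth, columns=matrix.samples)
    pd.concat([meta, depth], axis=1).to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path) -> CoverageMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    meta_cols = ["gene", "exon", "chrom", "start", "end"]
    samples = [c for c in df.columns if c not in meta_cols]
    exons = [
        (r.gene, int(r.exon), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    return CoverageMatrix(exons=exons, samples=samples, depth=df[samples].to_numpy(float))


# ---------------------------------------------------------------------------
# roh.bed  (0-based half-open on disk; 1-based inclusive in memory)

def write_roh_bed(segments: list[RohSegment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in segments:
            w.writerow([s.chrom, s.start - 1, s.end, s.patient_id, s.n_markers, s.n_het])


def read_roh_bed(path: str | Path) -> list[RohSegment]:
    segs: list[RohSegment] = []
    with open(path, newline="") as fh:
        for lineno, fields in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not fields:
                continue
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED fields")
            chrom, bstart, bend, pid, n_markers, n_het = fields[:6]
            segs.append(
                RohSegment(
                    patient_id=pid,
                    chrom=chrom,
                    start=int(bstart) + 1,
                    end=int(bend),
                    n_markers=int(n_markers),
                    n_het=int(n_het),
                )
            )
    return segs
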