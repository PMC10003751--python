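# Methods

`irdscape` implements the cohort-level analyses used to characterize the
molecular landscape of inherited retinal disease (IRD) in a clinic-based
cohort of index families: variant prioritization, a rule-based mapping
from genotype configurations to diagnostic status, autozygosity and
shared-haplotype mapping of founder alleles, exon-resolution CNV calling
from sequencing depth, splice-donor-shift arithmetic, and cohort summary
statistics.  A synthetic-cohort generator provides data with the same
statistical structure so that every stage is testable offline.

## Diagnostic classification

Each index patient's best candidate genotype within a single gene is an
*assortment*: one variant (het, hom or hemizygous) or a pair of
heterozygous variants with a phase relation (in trans, in cis, or
unknown).  The decision rules are:

| inheritance context | configuration | status |
|---|---|---|
| dominant | het P/LP | solved |
| recessive / isolated | two P/LP in trans, or hom P/LP | solved |
| X-linked, male | hemizygous P/LP | solved |
| recessive / isolated | P/LP + VUS in trans; two P/LP phase unknown | likely solved |
| recessive / isolated | two VUS in trans; P/LP+VUS or two VUS phase unknown; hom VUS | uncertain |
| dominant | het VUS | uncertain |
| X-linked, male | hemizygous VUS | uncertain |
| anything else | — incl. single het P/LP in a recessive gene, any in-cis pair | unsolved |

Design choices where the rules are silent:

- A homozygous P/LP is treated as two alleles in trans (solved):
  homozygosity is biallelic by construction, and homozygotes for
  recurrent founder deletions belong in the diagnosed set.
- Manifesting X-linked heterozygous females are a configurable policy,
  default `solved`; pipelines flag these patients in output so a
  reviewer can audit the call.
- Isolated cases, and the rare proband whose inheritance cannot be
  ascertained, follow the recessive rules.
- Diagnostic yield = (solved + likely solved) / index patients, rounded
  half-up to integer percent for report tables (174 of 230 → 76%).

The classifier is verified against an exhaustively enumerated,
independently hand-written truth table over the full cross-product of
inheritance × class combination × zygosity × phase, and satisfies a
monotonicity property: promoting any VUS to LP never lowers the status.

## Variant prioritization

Variants pass independent filters whose intersection is the kept set
(order cannot matter): a molecular-profile filter (nonsense, frameshift,
missense, splice-region, start-loss, in-frame indel, structural;
synonymous only when a splice prediction ≥ `splice_score_min` rescues
it), a population-frequency filter (MAF < 1%, missing MAF passes — novel
alleles have no population record), and for VUS a retention gate:
rare **and** protein-level or splice-predicted impact **and**
(GERP > 4 **or** splice prediction ≥ `splice_score_min`).  A missing
GERP fails the conservation arm: the gate is conservative on VUS,
permissive on novelty.  `splice_score_min` defaults to 0.6, below the
0.66 dbscSNV-ADA-style score of the motivating intronic variant, and is
configurable.  Candidate configurations are generated per compatible
inheritance mode (a single het is never a recessive candidate) and
reported by gene tier: curated disease-gene panel first, then
phenotype-database genes, then the rest of the genome.  The internal
inventory frequency check uses allele frequency; genotype-count
inventories would differ only for recurrent homozygotes.

## ROH calling and shared-haplotype mapping

Markers are biallelic genotypes (AA/AB/BB/missing) at known positions.
The caller slides a window of `window_markers` (default 50) allowing
`max_het_per_window` (default 1) heterozygous calls.  A candidate
segment is an inclusion-maximal run of at least one window's markers in
which every fully contained window passes; shorter runs carry no
window-level evidence and are never called.  Boundaries are trimmed to
the outermost homozygous markers (stable under window-size changes),
segments closer than `stitch_gap_bp` (default 500 kb) are stitched — a
handful of genotyping errors inside a long autozygous block otherwise
splits it — and results are filtered by `min_length_bp` (default 1 Mb)
and `min_markers` (default 25).  Missing genotypes neither break nor
anchor a run.  Defaults are chosen to recover Mb-scale segments at 3 kb
marker spacing with 0.2% heterozygous genotyping error; the windowed
caller is proven equal to an O(n²) brute-force enumeration oracle on
random tracks.

Total autozygosity is the summed segment length per genome in Mb,
excluding sex chromosomes (male hemizygosity is not autozygosity).
Shared regions are found by a sweep-line over segment endpoints: maximal
intervals covered by ≥ `min_patients` patients' ROHs, each reported with
its minimal critical region — the intersection of the supporting
segments, which localizes a founder allele.  Per-genotype-class summary
statistics use the lower-median convention.

## CNV calling from depth

Per-exon depth is library-size normalized (each sample scaled to the
cohort-median total), then divided by the leave-one-out median of the
other samples at the same exon, so a sample sequenced at half depth
genome-wide still shows ratios near 1 and exon-level capture efficiency
cancels.  Copy-state bands are ratio ≤ 0.15 (homozygous deletion),
0.35–0.65 (het deletion), ≥ 1.35 (duplication); these are this module's
own choices, exposed in config, since depth-based callers in the
literature do not print fixed thresholds.  Calls are maximal runs of
consecutive same-band exons within a gene, minimum one exon, no maximum.
No GC correction is applied (the synthetic data carries no GC bias); a
hook remains in config.

Breakpoint refinement scans a per-base depth track: for a homozygous
deletion, bases ≥ 50% of the flanking median are flank-like and bases
< 15% are event-like; the uncertainty interval runs from just after the
last flank-like base to the first event-like base on each side (a clean
step yields width-1 intervals), clipped to the flanking introns when a
gene model is supplied, and falling back to the whole intron when no
transition exists.  Het deletions and gains use analogous thresholds
around their expected ratios.  Point estimates are always reported with
their uncertainty intervals, since printed deletion coordinates may be
breakpoint-exact or not.

Deletion arithmetic is 1-based inclusive: `bp = end − start + 1`, with
kb rounded half-up to one decimal.  A junction PCR across a deletion
yields `product = template span − deleted length`, where the template
span is measured from the forward primer's 5' base to the reverse
primer's 3' base on the reference.

## Splice-donor-shift arithmetic

An alternative donor `s` exonic nucleotides upstream of the canonical
donor removes exactly `s` nucleotides from the transcript: frameshift
iff `s mod 3 ≠ 0`, else an in-frame loss of `s/3` codons; the RT-PCR
amplicon shrinks by exactly `s`.  Locating the premature stop of a
frameshifted isoform requires the transcript's coding sequence; without
one the function reports "requires transcript" rather than guessing.
Donor strength is consumed as an observation, never predicted.

## Landscape statistics

Allele occurrences count allele copies over index patients only
(hom = 2, het/hemi = 1), so eight homozygotes plus one heterozygous
carrier give 17 occurrences; affected relatives are excluded to keep the
denominator one-per-family.  The recurrence spectrum bins per-variant
occurrence counts into {1, 2, ≥3} and supports two denominators —
distinct variants and total causative alleles — because both conventions
appear in practice; neither is privileged.  The zygosity breakdown
assigns each diagnosed patient exactly one of AR-hom, AR-comp-het,
AD-het, XL-hemi, XL-het-female.  Birth-cohort trends report per-decade
lower medians of total autozygosity and the homozygous share among
diagnosed patients, excluding (and counting) patients without a birth
year.  Report percentages round half-up; TSV output keeps full
precision.

## Synthetic cohorts

The generator plants ground truth first and derives data from it; the
truth table (expected status, genotype class, causal variant ids, ROH
intervals) is emitted alongside and read only by tests.

Defaults describe the study conditions the pipeline was designed
around: 230 index families; inheritance mixture 48% isolated, 37%
recessive, 7% dominant, 7% X-linked, remainder unascertained; 76%
of cases receive a diagnosable genotype (8% uncertain, the rest
unsolved — the published figure splits only diagnosed vs not, so the
uncertain share is this package's choice); 51% of diagnosed recessive
genotypes homozygous, counted over solved *and* likely-solved recessive
cases (likely-solved configurations are two-variant by construction, so
all homozygotes come from the solved pool); 80% of X-linked index cases
male.  Founder alleles are planted at exactly their target occurrence
count — `h` homozygotes and `r` het carriers with `2h + r = target`,
`r` binomial with a 10% het-carrier rate — so the mean over seeds equals
the target by construction; the default list's top allele is a two-exon
deletion planted 17 times (eight homozygotes), and the default cohort
shows a recurrence-skewed spectrum (≈31% of causative alleles in
variants seen ≥3 times at n=230).  Steeper skews (e.g. 42% in the ≥3
bin) are planted via config in the recovery tests at n=500, where more
diagnosed-recessive slots make large founder lists feasible.

ROH lengths are exponential with a 5 Mb mean and a 1.5 Mb floor — a
one-parameter family matching the tens-of-Mb spread of per-genome
autozygosity without asserting a demographic model.  Background markers
are drawn independently (35% heterozygous) with no linkage
disequilibrium: the analysis consumes genotype runs, not haplotype
frequencies.  Planted intervals are homozygous apart from
Bernoulli(0.2%) het miscalls.  A config flag plants one homozygous
causal variant outside any ROH, emulating the occasional outlier.  The
generator does not model endogamy quantitatively and does not reproduce
a birth-year autozygosity trend by default; a trend can be planted via
config.

Exon depth is gamma-mixed Poisson (negative binomial) around
`depth_mean × copy_number / 2` with dispersion 0.01 (≈13% ratio CV at
150×, typical of leave-one-out exome ratios), modulated by per-exon
capture and per-sample library-size log-normal factors that downstream
normalization must remove.

All randomness flows through one `numpy.random.default_rng` integer
seed; a fixed seed reproduces a cohort byte-for-byte across platforms.

### What the generator does not emulate

No linkage disequilibrium, recombination maps, pedigrees or coalescent
realism; no GC bias or batch effects in depth; no mosaicism; no
population allele-frequency spectrum beyond the planted founder/private
dichotomy.  Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated noise models, not their
field performance on real array or exome data.

## Problem sizes and numerical choices

Recovery tests use 20 simulated tracks per scenario (50 patients for
the shared-haplotype scenario), 100 replicates for CNV
sensitivity/specificity, and cohorts of 500–1000 for fraction-recovery
checks — sizes at which the Monte-Carlo medians are stable to well
under the tolerances tested.  Ties in candidate ranking break by gene
tier; the lower-median convention is used for box-plot style summaries;
percentage rounding is half-up throughout.  Degenerate inputs (empty
cohorts, empty marker tracks, all-zero exons, all-missing birth years)
return empty results or raise informative errors as documented per
function.

## Known limitations

The diagnostic rules consume pre-assigned P/LP/VUS classes; no ACMG
evidence-code scoring is performed.  The prioritization module does not
compute annotation scores (GERP, splice predictors) — it filters on
them.  Mobile-element insertion detection, SNP-array intensity CNV
calling, repeat-homology scanning and phasing are out of scope.  The
X-linked heterozygous-female policy and the uncertain-fraction default
are pragmatic choices, documented above, not established conventions.
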