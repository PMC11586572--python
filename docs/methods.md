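# Methods

`triomap` implements the computational core of a trio whole-genome study of
a rare congenital recessive defect in a livestock population: two affected
paternal half-sibs, their two dams and the common sire are sequenced, a
candidate causal variant is prioritized by Mendelian filtering against
control cohorts and by homozygosity mapping, structural causes are screened
from read depth, and the candidate alleles are then genotyped across the
breeding population. This note documents the models, the defaults and the
design choices, and states what the synthetic data do and do not show.

## Inheritance scenarios and the filtering cascade

Two fully penetrant single-locus models are screened:

* **Recessive homozygous.** Both cases carry genotype var/var; every
  sequenced parent is an obligate carrier (ref/var). Control cohorts may
  contain heterozygous carriers but no homozygote (`EXCLUDE_IF_HOM_ALT`).
* **Paternal germline de novo.** A dominant allele that arose in the
  sire's germ line: ref/var in the sire's (semen-derived) sample and both
  cases, ref/ref in the dams, and absent entirely from controls
  (`EXCLUDE_IF_ANY_ALT`).

The cascade applies, in a fixed order: (1) trio genotype pattern,
(2) protein-changing impact (snpEff classes MODERATE or HIGH),
(3) local control-cohort exclusion, (4) global control-catalog exclusion.
Counts in and out of each step are reported. The three post-pattern steps
are independent per-variant predicates, so the final candidate set is
invariant under their permutation (a tested property); only the per-step
counts depend on the order. "Private" means absence under the scenario's
policy from the control cohorts; no allele-frequency threshold is used.

Missing genotypes are treated asymmetrically, on purpose: a missing call
in the trio fails the pattern (the trio genotypes are treated as confirmed
calls), while missing calls in a control cohort reduce its denominator but
never veto an exclusion decision (controls are an occurrence catalog).
Half-missing VCF genotypes (`./1`) are collapsed to missing — a half call
never certifies a genotype class. Multi-allelic sites are split into
biallelic records; in the view of one alternate allele, a genotype
containing any other alternate allele is undefined and therefore missing.
Visual read-level review of candidates (IGV-style) is out of computational
scope; the filter report carries a free-text `manual_review` field instead.

## Runs of homozygosity and shared IBD regions

A recessive allele inherited identical-by-descent through both parental
lines sits inside a long run of homozygosity (ROH) in each affected
animal. Detection uses a deterministic **consecutive-runs scanner** rather
than a sliding-window heuristic: a run is a maximal window of consecutive
markers whose endpoints are homozygous, with at most `max_het_in_run`
heterozygous calls (default 1), at most `max_missing_in_run` missing calls
(default 5), and no adjacent-marker gap above `max_gap_kb` (default
1000 kb); runs shorter than `min_length_kb` (default 1000 kb, the standard
threshold for WGS homozygosity mapping in cattle) or with fewer than
`min_snps` markers (default 50) are discarded. Maximality is by set
inclusion; two maximal runs may overlap when the heterozygote budget can
be spent on either flank, and both are reported. The scanner is checked
against an exhaustive window enumerator on random data.

Two cases' overlapping runs form a **shared IBD region** only after
allelic matching: over the jointly non-missing markers in the positional
overlap, the fraction of identical genotypes must reach `match_threshold`
(default 0.95, the standard allelic-matching threshold). At least
`min_joint_snps` (default 20) jointly called markers are required — a
match fraction over a handful of markers certifies nothing.

Each region is annotated per parent with obligate-carrier compatibility:
the parent is `HETEROZYGOUS_COMPATIBLE` iff at least one marker in the
region has both cases homozygous-alt and the parent heterozygous. The
published account of such segments ("parents heterozygous") does not
define a per-marker criterion, so this is a design choice. The obvious
stricter rule — additionally requiring the parent to be homozygous-alt
nowhere in the region — turns out to reject essentially every true region:
common alleles riding the shared haplotype routinely make a parent
homozygous at some shared site without refuting carrier status at a *rare*
candidate, which is only ever at sites where the parent is heterozygous.

Coordinates are 1-based inclusive throughout (VCF/PLINK `.hom`
convention); lengths are `end − start + 1`; BED output converts to 0-based
half-open on write. Sex chromosomes can be excluded from ROH and from the
depth baseline via a configurable list (both candidate loci in the
motivating study are autosomal).

## Read-depth screen

Binned mean depth (default 10 kb bins, consumed pre-binned from TSV — BAM
processing is out of scope) is normalized by the sample's autosomal median
bin depth, making the nominal coverage level (≈18× in the emulated study)
irrelevant and the screen scale-invariant. A chromosome is flagged by its
median normalized ratio, a queried region by its mean ratio, against a
diploid band of [0.75, 1.25] — midway between the two-copy expectation
(1.0) and the one-copy (0.5) / three-copy (1.5) expectations. A queried
region with no bins reports `NO_DATA` rather than erroring. The thresholds
are configuration, not biology: the motivating analysis reports none.

## Population segregation

Targeted genotyping of the breeding population is summarized as
genotype-class counts per cohort. The variant-allele frequency is
`q̂ = (n_het + 2·n_homvar) / 2N` with a Wilson score 95% interval on the
2N allele trials (Wilson rather than Wald because carrier alleles are
rare; the interval is an addition of this package — carrier screens of
this kind usually report only a rounded percentage). Missing genotypes
are excluded from every denominator, and N is reported per locus — the
screen cohort need not have equal denominators across loci (genotyping
failures differ by assay).

The digenic co-segregation table classifies every dually genotyped
individual into the 3×3 joint genotype grid and issues verdicts: the
digenic-recessive model is *consistent* iff every affected individual is
var/var at both loci and no unaffected individual is; an unaffected
individual homozygous at one locus alone refutes the corresponding
fully penetrant monogenic model (`monogenic-<locus>-inconsistent`) while
leaving the digenic model alive. A cohort with no var/var genotype at
either locus is vacuously consistent and flagged `uninformative`.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
deterministically from a seed. Defaults mirror the emulated study where it
states numbers, and standard practice where it does not:

| parameter | default | meaning |
|---|---|---|
| `n_chroms` × `chrom_length_bp` | 5 × 20 Mb | scaled-down genome |
| `markers_per_mb` | 100 | ~10,000 biallelic background variants |
| `af_beta` | Beta(0.2, 2) | allele-frequency spectrum, rare-skewed |
| `n_local_controls` | 942 | per-sample local control cohort |
| `n_global_controls` | 5279 | global cohort, counts catalog only |
| `n_screened_bulls` | 332 | targeted-genotyping cohort, years 2017–2020 |
| `ancestral_haplotype_length_kb` | 2000 | planted IBD core interval |
| `recombination_rate_per_mb` | 0.01 | 1 crossover / 100 Mb / meiosis |
| impact spectrum | 93/3/3/1% | MODIFIER/LOW/MODERATE/HIGH |
| depth | 18.2× mean, cv 0.15, 10 kb bins | Gaussian bin noise |

Founder haplotypes are independent Bernoulli(q) draws per marker (no
background linkage disequilibrium — a stated non-goal); offspring gametes
recombine parental haplotypes with Poisson crossovers, so every
non-injected transmission is Mendelian-consistent by construction (and
checked by an independent Mendel-error checker in the tests).

Injections: a **recessive IBD** variant rides an ancestral core haplotype
shared by all three founders and transmitted through all four meioses
(cases hom-alt, parents het, a shared homozygous run around the locus,
shortened only by recombination); a **paternal de novo** variant is
conditioned through the sire's gametes only; a **digenic pair** plants two
recessive variants on different chromosomes plus one *screened bull*
homozygous at exactly the first locus — the sentinel unaffected animal.
That bull sits in the genotyping cohort, not among the WGS controls: a
homozygote in the control catalog would (correctly) exclude the variant
from the cascade, which is not the configuration being emulated.

One deliberate departure from a fully faithful transmission model: the
gamete's crossover phase is re-randomized at the boundaries of each
planted core interval, so linkage to the conditioned locus never leaks
beyond the planted segment. Markers outside core intervals therefore
follow the *unconditional* transmission model exactly, which makes the
cascade-survival probability of a background marker with frequency q
closed-form:

    P_recessive(q) = [2q(1−q)]³/16 · 1{protein-changing} · (1−q²)^(N_local+N_global)
    P_denovo(q)    = 2q(1−q)·(1−q)⁴/4 · 1{protein-changing} · (1−q)^(2(N_local+N_global))

(three founders het; four conditioning-free gametes transmit the allele;
no disqualifying genotype among controls). Observed background survivors
are compared to the summed per-marker probabilities as a Poisson-binomial
count within 3σ, excluding markers inside planted cores (their
transmission is conditioned, and the hitchhikers they produce — variants
that survive the cascade because they ride the shared haplotype — are a
realistic feature, not background).

The deterministic carrier-screen fixture reproduces, per individual, a
published association-table configuration exactly: trio var/var // het at
both loci, screened bulls with genotype-class counts (296, 32, 1) and
(321, 11, 0) (the first locus has 3 genotyping failures, hence N = 329 vs
332), one bull homozygous at the first locus and reference at the second,
and external-control rows kept as counts. From those counts the
allele-frequency operation returns 5% and 2% after integer rounding.

**What passing tests do not show.** The generator has no background LD, no
genotyping error in the trio, uniform marker spacing, SNV-only variants,
Gaussian depth noise without GC or mappability structure, and a scaled
genome. Recovery rates and false-positive bounds established here are
properties of this model, not guarantees on real WGS data; in particular,
real data would add IGV-style manual review between the cascade and the
final candidate list.

## Problem sizes and numerical choices

Stochastic properties are established over 100 generator seeds (20 for
the full cascade, which dominates runtime) at the default cohort sizes —
enough for the binomial tolerances used (≥95/100, ≥93/100, 3σ). The
Wilson-coverage check plants q = 0.015 in a cohort of 332 (a realistic
rare recessive carrier allele in a screen of this size; exact interval
coverage there is 96.5%, comfortably above the nominal target given
coverage oscillation of score intervals). Ties and degenerate inputs:
empty record lists flow through every filter and report zero counts;
regions with no depth bins are `NO_DATA`; an all-missing genotype group
reports an undefined carrier fraction rather than 0; zero jointly called
markers yield *no* match rather than a vacuous match of 1.0.
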