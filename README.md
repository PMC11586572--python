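# triomap

Trio-based whole-genome variant prioritization for rare recessive defects
in livestock: Mendelian genotype-pattern filtering under competing
inheritance scenarios, shared runs-of-homozygosity (IBD) mapping,
read-depth structural screening, and population carrier-frequency /
digenic segregation analysis — plus a deterministic synthetic
pedigree-cohort generator for testing the whole pipeline without any data
download.

## Who this is for

Veterinary and livestock geneticists prioritizing candidate causal
variants from a small sequenced pedigree — typically two affected
half-sibs, their dams and the common sire — against local and global
control cohorts, and then quantifying carrier prevalence of the resulting
candidate alleles in the breeding population.

## The model

Two fully penetrant single-locus scenarios are screened over every
biallelic variant with per-sample alt dosages g ∈ {0, 1, 2}:

* **recessive homozygous** — cases g = 2, all parents g = 1 (obligate
  carriers); controls may be carriers but never homozygous;
* **paternal germline de novo** — sire and cases g = 1, dams g = 0;
  controls carry no variant allele at all.

The filtering cascade is: genotype pattern → protein-changing impact
(MODERATE/HIGH) → absent in the local control cohort → absent in the
global control catalog, with per-step counts reported.

Homozygosity mapping detects per-case ROH with a consecutive-runs scanner
(runs ≥ 1000 kb, ≤ 1 heterozygous and ≤ 5 missing calls, endpoints
homozygous) and certifies shared IBD regions by allelic matching of the
overlap (identical-genotype fraction ≥ 0.95 over ≥ 20 jointly called
markers), annotating each parent for obligate-carrier compatibility.

For a genotyped cohort with genotype-class counts (n_rr, n_rv, n_vv) the
variant-allele frequency is

    q̂ = (n_rv + 2·n_vv) / 2N,   N = n_rr + n_rv + n_vv,

with a Wilson score 95% interval on the 2N allele trials. The digenic
co-segregation table asks whether disease requires homozygosity at two
loci simultaneously: consistent iff every affected individual is var/var
at both and no unaffected individual is.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Simulate a scaled synthetic cohort (40 markers/Mb, 50 local controls, a
200-genome global catalog, 332 screened bulls) and analyze it:

```sh
cat > sim.yaml <<'YAML'
markers_per_mb: 40.0
n_local_controls: 50
n_global_controls: 200
n_screened_bulls: 332
YAML
triomap simulate --seed 42 --out cohort --config sim.yaml

cat > run.yaml <<'YAML'
vcf: cohort/cohort.vcf
pedigree: cohort/pedigree.tsv
global_catalog: cohort/global_catalog.tsv
depth_tsvs: [cohort/depth_case1.tsv, cohort/depth_case2.tsv]
bull_genotypes: cohort/bull_genotypes.tsv
roh: {min_snps: 25, min_joint_snps: 10}   # scaled marker density
out_dir: results
YAML
triomap analyze --config run.yaml
```

which prints the cascade and mapping summary:

```
INFO:triomap:loaded 4003 variant records, 55 samples
INFO:triomap:recessive/genotype_pattern: 4003 -> 10
INFO:triomap:recessive/protein_changing_impact: 10 -> 2
INFO:triomap:recessive/absent_in_local_controls: 2 -> 2
INFO:triomap:recessive/absent_in_global_catalog: 2 -> 2
INFO:triomap:denovo/genotype_pattern: 4003 -> 68
INFO:triomap:denovo/protein_changing_impact: 68 -> 5
INFO:triomap:denovo/absent_in_local_controls: 5 -> 1
INFO:triomap:denovo/absent_in_global_catalog: 1 -> 1
INFO:triomap:shared IBD regions: 7 (max 2925.0 kb on 5 chromosomes)
recessive: 2 candidate(s)
denovo: 1 candidate(s)
```

The two recessive candidates (`2:10000000A>T`, `4:10000000T>A`) are
exactly the planted recessive pair (see `cohort/truth.json`), each flagged
as contained in a shared IBD region in `results/report.json`; the single
de novo candidate is the planted paternal-germline variant. Reading the
cascade: 4003 variants enter; 10 match the recessive trio pattern (the
planted pair plus hitchhikers riding the shared haplotype); 2 are
protein-changing; none is seen in a control, so 2 survive.

Carrier screening of the bull cohort:

```
$ triomap segregate --genotypes cohort/bull_genotypes.tsv --out seg
2:10000000A>T: q=0.0693 (7%)
4:10000000T>A: q=0.0166 (2%)
digenic verdicts: digenic-consistent, monogenic-2:10000000A>T-inconsistent
```

— the planted carrier frequencies are recovered, and the one simulated
bull homozygous at the first locus but wild-type at the second refutes a
fully penetrant monogenic model at that locus while leaving the digenic
model consistent, mirroring the configuration such screens look for.

Other subcommands (`filter`, `roh`, `depth`) run one stage each on the
same file formats; `python -m triomap.cli --help` lists them.

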