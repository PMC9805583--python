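# vcfmerge

Merge batch-imputed, position-sorted VCF files into a single cohort VCF,
with statistically sound combination of per-batch imputation quality.

## The problem

Genotype imputation servers (TOPMed, Michigan) cap the number of samples
per submission, so large cohorts are imputed in batches: each batch comes
back as a per-chromosome `*.vcf.gz` plus a Minimac-style `*.info.gz`
table carrying, per variant, the ALT allele frequency (AF), minor allele
frequency (MAF), imputation quality R² and genotyped status. Downstream
association analysis needs one VCF per chromosome covering every sample,
which raises four problems general-purpose VCF tools handle poorly:

1. **Imputation quality must be combined correctly.** R² is a squared
   correlation; its sampling distribution is skewed, so per-batch values
   cannot simply be averaged. `vcfmerge` applies Fisher's
   variance-stabilizing z-transformation: for batch *i* with quality
   R²ᵢ and nᵢ samples,

       rᵢ = √R²ᵢ,   zᵢ = arctanh(rᵢ),
       z̄ = Σ wᵢ zᵢ / Σ wᵢ   (wᵢ = nᵢ, or nᵢ − 3),
       R²_combined = tanh(z̄)².

2. **Variants are not shared by all batches.** A `--missing` allowance
   controls how many batches a variant may be absent from before it is
   dropped; retained variants get `.|.` genotypes for all samples of the
   batches that lack them.

3. **Samples may be duplicated across batches.** Duplicates are kept as
   distinct columns under suffixed IDs (`ID`, `ID:2`, …) and listed in
   `duplicates.txt`.

4. **Scale.** Batches are merged in a single synchronized forward scan —
   every input line is read at most once and nothing is loaded whole —
   and the output is block-gzipped (BGZF) so it can be indexed.

AF and MAF are summarized across batches as sample-count-weighted means
together with per-batch minima and maxima; genotyped status is reported
as `all` / `some` / `none`.

## Worked example

Generate a small synthetic two-batch cohort (10 individuals, 30 variants,
one sample present in both batches, one variant private to batch 0) and
merge it:

```python
from vcfmerge import CohortSpec, generate_cohort, split_into_batches
cohort = generate_cohort(CohortSpec(n_samples=10, n_variants=30, seed=1))
split_into_batches(cohort, "demo", k=2, overlap=1, private_variant_counts=[1, 0])
```

```bash
vcfmerge --input demo/batch0.vcf.gz --input demo/batch1.vcf.gz \
         --missing 1 --rsq-threshold 0.3 --out demo/merged --verbose
```

prints

```
retained variants:           30
excluded (too-many-missing): 0
excluded (below-threshold):  0
output samples:              11
duplicated sample IDs:       1
merged VCF:                  demo/merged.vcf.gz
```

All 30 variants pass: the private variant is absent from only one batch
(within `--missing 1`) and every combined R² clears 0.3. The 11 output
columns are the 5 + 6 batch samples; the individual present in both
batches appears twice (`S0000` and `S0000:2`) and is listed in
`duplicates.txt`. Besides `merged.vcf.gz` the run writes
`merged_retained.info.txt` / `merged_excluded.info.txt` (combined and
per-batch AF, MAF, R², genotyped status, and the exclusion reason) and
`merged.log`.

In the merged VCF the INFO column carries the combined values, e.g.

```
AF=0.354083;MAF=0.354083;R2=0.662963;IMPUTED;TYPED_STATUS=none
```

— the weighted-mean AF/MAF, the Fisher-combined R², and the cross-batch
genotyped status appended as `TYPED_STATUS`.

If a batch lacks an info table (VCF not produced by an imputation
server), `--make-info` derives one from the AF/MAF/R2/TYPED annotations
in the VCF INFO column first.

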