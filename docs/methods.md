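# Methods

## Statistical model

### Combining imputation quality

Imputation servers report, per variant and batch, the estimated squared
correlation R² between imputed dosage and true genotype. Correlation
estimates have a skewed sampling distribution, increasingly so near |r| = 1,
so R² values are combined on Fisher's z scale, where the distribution is
approximately normal with variance independent of r:

    r_i = sqrt(R²_i)
    z_i = arctanh(r_i)
    z̄  = Σ w_i z_i / Σ w_i
    R²_combined = tanh(z̄)²

The nonnegative root is taken because info files report only R², never the
sign of the underlying dosage–genotype correlation. Before `arctanh`, r is
clamped to 1 − 10⁻⁶: genotyped variants legitimately carry R² = 1, which
would otherwise map to an infinite z. The clamp bounds the combined value
at (1 − 10⁻⁶)² ≈ 1 − 2·10⁻⁶, far inside the precision of reported
quality scores.

**Weights.** The default weight is the batch sample count n (the variant
being present in that batch). The classical standard error of z is
1/√(n − 3), which suggests w = n − 3; both conventions are implemented
(`weight_mode = "n"` or `"n-3"`). The default is n because it matches the
allele-frequency weighting, is well defined for batches of ≤ 3 samples,
and differs from n − 3 negligibly at the hundreds-to-thousands scale where
batch imputation is used. Individuals in batches lacking the variant are
not counted: absent batches contribute no term. A batch that contains the
variant but reports a placeholder quality ('-', '.', empty) contributes to
AF/MAF and genotyped status but not to the z-combination; if no batch
reports quality, the combined value is absent and cannot fail the
threshold.

The implementation sums the weighted z terms in a canonical order (sorted
by z, then weight), so the result is bitwise identical under any
permutation of the input batches.

### Allele-frequency summaries

AF and MAF are combined as weighted means with the same weights, plus the
minimum and maximum over contributing batches. When batch AFs are computed
from dosages and weights equal batch sample counts, the weighted mean
equals the AF of the pooled dosage vector exactly (up to float rounding;
the test suite asserts 10⁻⁹).

### Genotyped status

Per variant: `all` if every contributing batch flags it genotyped, `none`
if none does, `some` otherwise.

## Variant selection

The union of variant keys — the exact tuple (chrom, pos, REF, ALT); no
allele normalization — across all batch info tables is classified by two
rules in a fixed order, so the recorded exclusion reason is deterministic:

1. absent from more than `missing_allowance` batches → excluded,
   reason `too-many-missing`;
2. otherwise, combined R² present and below `rsq_threshold` → excluded,
   reason `below-threshold`.

The threshold is applied uniformly; variants genotyped in every batch are
not exempted (their R² is typically 1, so the point is moot in practice).
Defaults are `missing_allowance = 0` (variant must be in all batches) and
`rsq_threshold = 0`: the conservative missingness default avoids silently
inflating the output with `.|.` cells. Combined statistics are computed
for excluded variants too, so the excluded table is a usable audit trail.
Retained variants are ordered by (pos, REF, ALT); the allele tie-break at
equal positions is a determinism convention of this package.

## The streaming merge

All input VCFs are opened simultaneously and consumed strictly forward.
For each retained variant, each containing batch's stream is advanced to
the variant's position; all records at one position are buffered in a
small dict so that allele order within a position may differ between files
without breaking the scan. Every line is read at most once and the scan
never rewinds. A variant announced by a batch's info table but not found
in its VCF is a desynchronization error; decreasing positions within a
file are a fatal sort-order error (sortedness is an input contract, and
silent resorting would break the single-pass design). After the last
retained variant, each stream is drained to verify the VCF and info tables
have equal record counts.

Row assembly: CHROM–FILTER, FORMAT and unrecognized INFO tokens come from
the first batch containing the variant (which batch donates QUAL/FILTER is
unspecified territory; first-present is this package's documented
convention). Genotype columns are concatenated in batch order; a batch
lacking the variant contributes `.|.` in the GT slot and `.` in every
other FORMAT slot for each of its samples. A present batch whose FORMAT
string differs from the donor's is an error, not a repair — imputation
outputs are uniform (`GT:DS` or `GT:DS:GP`), and silently reordering
subfields would corrupt dosages. In INFO, the AF, MAF and R2/Rsq tokens
are replaced by the combined values (inserted if the donor lacked them)
and `TYPED_STATUS=<all|some|none>` is appended; everything else is passed
through byte-faithfully.

Duplicate sample IDs across batches: the first occurrence keeps its ID,
the j-th later occurrence becomes `ID:j+1` (with a further `.k` suffix in
the pathological case where that name already exists), and every shared ID
is written to `duplicates.txt`. The suffix scheme is this package's
convention.

Output is BGZF (block gzip), written through pysam's BGZF codec or, when
`threads > 1`, piped through the `bgzip` executable. Parallelism is
confined to compression; the merge logic is a deterministic single scan,
so decompressed output bytes are identical for any thread count. On any
fatal error the partial VCF is deleted — a truncated BGZF file is a silent
downstream hazard.

## Synthetic cohorts

The `fixtures` module generates the test data: per-variant ALT
frequencies drawn uniformly from a configurable range (default
0.05–0.95), two independent Bernoulli(AF) alleles per sample, dosage =
genotype + uniform noise on ±0.1 truncated to [0, 2], and the AF
annotation recomputed from realized dosages as a server would report it.
Per-batch R² values are *assigned*, not estimated — the merger consumes
R² as given, so tests need exact known inputs rather than an imputation
error model. The splitter partitions samples into contiguous groups,
optionally re-adds leading samples of group 0 to group 1 (true
duplicates) and designates variants private to single batches, then
writes batch VCF/info pairs in the same dialects the readers accept plus
a ground-truth manifest (presence vectors, per-batch and pooled AFs,
per-batch R²).

What this emulates and what it does not: file dialects, missingness
patterns, duplicates and the statistical identities are faithful; linkage
disequilibrium, population structure, realistic imputation error and
multiallelic complexity are not simulated. Passing tests therefore
establish the correctness of the merging and combination logic, not
robustness to every dialect drift seen in the wild.

## Numerical and interface choices

- Numbers in info outputs and rewritten INFO fields carry up to 6
  significant digits, matching server output precision; manifest values
  used in identity tests are kept at full float64 precision.
- Info-table column dialects are detected case-insensitively over the
  synonym sets {Rsq, R2}, {ALT_Frq, AF, ALT_frq}, {Genotyped, TYPED};
  the detected dialect is recorded in the run log.
- An unsplit multiallelic ALT string ("G,T") is one record keyed on the
  full string; it matches split records in another batch only on exact
  equality and otherwise surfaces as missing.
- `read_info_table` bounds-checks AF ∈ [0,1], MAF ∈ [0,0.5], R² ∈ [0,1]
  and names the offending row.
- The acceptance script runs the pipeline at 3 batches × ~100 samples ×
  2000 variants and the oracle comparisons at 1000 random cases — sizes
  chosen so the whole reproduction completes in seconds while every code
  path (duplicates, private variants, both exclusion rules) is exercised.

## Known limitations

- One chromosome per input file; no cross-chromosome orchestration.
- No tabix index creation, no BCF output, no allele left-alignment.
- Genotype concordance between duplicated samples is not checked; both
  copies are emitted verbatim.
- Empirical R² (ER2) is not combined; only the standard quality score is.
- The `n − 3` weight mode errors on batches of ≤ 3 samples by design.
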