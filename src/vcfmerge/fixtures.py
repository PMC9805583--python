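"""Synthetic imputed-cohort generator with known ground truth.

Real imputation-server output (dbGaP-controlled cohorts) cannot ship with
a test suite, so every other module is exercised against cohorts built
here: per-variant ALT frequencies, two Bernoulli(af) alleles per sample,
dosages equal to the genotype plus bounded uniform noise truncated to
[0, 2], and per-batch Rsq values that are *assigned*, not estimated — the
merger consumes Rsq as given, so tests need exact known inputs rather
than a realistic imputation error model. No linkage disequilibrium or
population structure is simulated.

``split_into_batches`` writes batch VCF/info file pairs in the same
dialect the readers accept, optionally duplicating samples across batches
and making designated variants private to one batch, and returns a
manifest holding the ground truth (presence vectors, per-batch and pooled
allele frequencies) that tests compare against.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats import VariantKey

__all__ = ["CohortSpec", "Cohort", "BatchSetManifest", "generate_cohort", "split_into_batches"]


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_samples: int
    n_variants: int
    chrom: str = "chr1"
    af_range: tuple[float, float] = (0.05, 0.95)
    genotyped_fraction: float = 0.2
    dosage_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("n_samples and n_variants must be >= 1")
        lo, hi = self.af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("af_range must lie strictly inside (0, 1)")
        if not 0.0 <= self.genotyped_fraction <= 1.0:
            raise ValueError("genotyped_fraction must be in [0, 1]")


@dataclass
class Cohort:
    """In-memory cohort: genotype/dosage matrices plus variant annotations."""

    spec: CohortSpec
    sample_ids: list[str]
    keys: list[VariantKey]
    genotypes: np.ndarray  # (n_variants, n_samples, 2) alleles in {0,1}
    dosages: np.ndarray  # (n_variants, n_samples) in [0,2]
    true_af: np.ndarray  # per-variant frequency used for simulation
    realized_af: np.ndarray  # AF recomputed from the realized dosages
    genotyped: np.ndarray  # per-variant bool

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class BatchSetManifest:
    """Ground truth for a generated batch set."""

    batch_sample_ids: list[list[str]]
    batch_sample_idx: list[np.ndarray]
    presence: dict[VariantKey, list[bool]]
    batch_af: dict[VariantKey, list[float | None]]
    pooled_af: dict[VariantKey, float]
    batch_rsq: dict[VariantKey, list[float | None]]
    duplicated_ids: list[str] = field(default_factory=list)
    vcf_paths: list[Path] = field(default_factory=list)
    info_paths: list[Path] = field(default_factory=list)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate one cohort; deterministic under ``spec.seed``.

    Each sample carries two independent Bernoulli(af) alleles per variant;
    the dosage is the allele sum plus uniform noise on
    [-dosage_noise, +dosage_noise] truncated to [0, 2]. The AF annotation
    is recomputed from the realized dosages (mean dosage / 2), as an
    imputation server would report it.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_variants, spec.n_samples
    lo, hi = spec.af_range
    true_af = rng.uniform(lo, hi, size=m)
    genotypes = (rng.random((m, n, 2)) < true_af[:, None, None]).astype(np.int8)
    noise = rng.uniform(-spec.dosage_noise, spec.dosage_noise, size=(m, n))
    dosages = np.clip(genotypes.sum(axis=2) + noise, 0.0, 2.0)
    realized_af = dosages.mean(axis=1) / 2.0
    genotyped = rng.random(m) < spec.genotyped_fraction
    positions = np.sort(rng.choice(np.arange(1_000, 1_000 + 50 * m), size=m, replace=False))
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    keys = [
        VariantKey(
            chrom=spec.chrom,
            pos=int(positions[j]),
            ref=str(bases[ref_idx[j]]),
            alt=str(bases[(ref_idx[j] + alt_shift[j]) % 4]),
        )
        for j in range(m)
    ]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return Cohort(
        spec=spec,
        sample_ids=sample_ids,
        keys=keys,
        genotypes=genotypes,
        dosages=dosages,
        true_af=true_af,
        realized_af=realized_af,
        genotyped=genotyped,
    )


def _write_batch_vcf(
    path: Path,
    chrom: str,
    sample_ids: list[str],
    keys: list[VariantKey],
    genotypes: np.ndarray,
    dosages: np.ndarray,
    af: np.ndarray,
    rsq: list[float | None],
    genotyped: np.ndarray,
) -> None:
    with gzip.open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="ALT allele frequency">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R-squared">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped on array">\n')
        fh.write('##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Imputed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, key in enumerate(keys):
            maf = min(af[j], 1.0 - af[j])
            info = [f"AF={af[j]:.6g}", f"MAF={maf:.6g}"]
            if rsq[j] is not None:
                info.append(f"R2={rsq[j]:.6g}")
            info.append("TYPED" if genotyped[j] else "IMPUTED")
            cells = [
                f"{genotypes[j, i, 0]}|{genotypes[j, i, 1]}:{dosages[j, i]:.3f}"
                for i in range(len(sample_ids))
            ]
            fh.write(
                "\t".join(
                    [key.chrom, str(key.pos), str(key), key.ref, key.alt, ".", "PASS",
                     ";".join(info), "GT:DS"] + cells
                )
                + "\n"
            )


def _write_batch_info(
    path: Path,
    keys: list[VariantKey],
    af: np.ndarray,
    rsq: list[float | None],
    genotyped: np.ndarray,
) -> None:
    with gzip.open(path, "wt") as fh:
        fh.write("SNP\tREF(0)\tALT(1)\tALT_Frq\tMAF\tAvgCall\tRsq\tGenotyped\n")
        for j, key in enumerate(keys):
            maf = min(af[j], 1.0 - af[j])
            rsq_s = "-" if rsq[j] is None else f"{rsq[j]:.6g}"
            fh.write(
                f"{key}\t{key.ref}\t{key.alt}\t{af[j]:.6g}\t{maf:.6g}\t-\t{rsq_s}\t"
                + ("Genotyped" if genotyped[j] else "Imputed")
                + "\n"
            )


def split_into_batches(
    cohort: Cohort,
    out_dir: str | Path,
    k: int,
    overlap: int = 0,
    private_variant_counts: list[int] | None = None,
    rsq_by_batch: np.ndarray | None = None,
    prefix: str = "batch",
) -> BatchSetManifest:
    """Write ``k`` batch (vcf.gz, info.gz) pairs plus the ground-truth manifest.

    Samples are partitioned into ``k`` contiguous groups; the first
    ``overlap`` samples of group 0 are re-added to group 1 under the same
    IDs, creating true cross-batch duplicates. ``private_variant_counts[b]``
    designates that many variants (taken round-robin from the cohort) as
    present *only* in batch b — all other batches drop them.
    ``rsq_by_batch`` (shape k x n_variants) assigns per-batch quality;
    genotyped variants default to Rsq 1.0 and imputed ones to values in
    [0.3, 1.0] drawn from the cohort seed.

    Per-batch AF is recomputed from that batch's dosage columns, so the
    manifest's pooled AF (over the concatenated columns, duplicates
    included) exactly equals the sample-count-weighted mean of batch AFs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n, m = cohort.n_samples, len(cohort.keys)
    if k < 1:
        raise ValueError("k must be >= 1")
    bounds = np.linspace(0, n, k + 1).astype(int)
    groups = [np.arange(bounds[b], bounds[b + 1]) for b in range(k)]
    if any(len(g) == 0 for g in groups):
        raise ValueError(f"cannot split {n} samples into {k} non-empty batches")
    duplicated_ids: list[str] = []
    if overlap:
        if k < 2 or overlap >= min(len(g) for g in groups):
            raise ValueError("overlap must be smaller than the smallest batch")
        dup_idx = groups[0][:overlap]
        groups[1] = np.concatenate([dup_idx, groups[1]])
        duplicated_ids = [cohort.sample_ids[i] for i in dup_idx]

    private = private_variant_counts or [0] * k
    if len(private) != k:
        raise ValueError("private_variant_counts must have one entry per batch")
    if sum(private) > m:
        raise ValueError("more private variants requested than variants in the cohort")
    # assign private variants from the front of the key list, batch by batch
    owner = np.full(m, -1)  # -1: shared by all batches
    j = 0
    for b, cnt in enumerate(private):
        owner[j : j + cnt] = b
        j += cnt

    if rsq_by_batch is None:
        rng = np.random.default_rng(cohort.spec.seed + 1)
        rsq_by_batch = np.where(
            cohort.genotyped[None, :], 1.0, rng.uniform(0.3, 1.0, size=(k, m))
        )
    rsq_by_batch = np.asarray(rsq_by_batch, dtype=float)
    if rsq_by_batch.shape != (k, m):
        raise ValueError(f"rsq_by_batch must have shape ({k}, {m})")

    presence: dict[VariantKey, list[bool]] = {}
    batch_af: dict[VariantKey, list[float | None]] = {}
    batch_rsq: dict[VariantKey, list[float | None]] = {}
    pooled_af: dict[VariantKey, float] = {}
    vcf_paths: list[Path] = []
    info_paths: list[Path] = []
    batch_sample_ids = [[cohort.sample_ids[i] for i in g] for g in groups]

    for b in range(k):
        keep = np.flatnonzero((owner == -1) | (owner == b))
        g = groups[b]
        af_b = cohort.dosages[np.ix_(keep, g)].mean(axis=1) / 2.0
        keys_b = [cohort.keys[j] for j in keep]
        rsq_b: list[float | None] = [float(rsq_by_batch[b, j]) for j in keep]
        vcf_path = out_dir / f"{prefix}{b}.vcf.gz"
        info_path = out_dir / f"{prefix}{b}.info.gz"
        _write_batch_vcf(
            vcf_path, cohort.spec.chrom, batch_sample_ids[b], keys_b,
            cohort.genotypes[keep][:, g], cohort.dosages[np.ix_(keep, g)],
            af_b, rsq_b, cohort.genotyped[keep],
        )
        _write_batch_info(info_path, keys_b, af_b, rsq_b, cohort.genotyped[keep])
        vcf_paths.append(vcf_path)
        info_paths.append(info_path)
        for row, j_var in enumerate(keep):
            key = cohort.keys[j_var]
            presence.setdefault(key, [False] * k)[b] = True
            batch_af.setdefault(key, [None] * k)[b] = float(af_b[row])
            batch_rsq.setdefault(key, [None] * k)[b] = rsq_b[row]

    # pooled AF over the concatenated sample columns (duplicates included),
    # restricted to the batches containing the variant
    for j_var, key in enumerate(cohort.keys):
        cols = [groups[b] for b in range(k) if presence[key][b]]
        idx = np.concatenate(cols)
        pooled_af[key] = float(cohort.dosages[j_var, idx].mean() / 2.0)

    return BatchSetManifest(
        batch_sample_ids=batch_sample_ids,
        batch_sample_idx=groups,
        presence=presence,
        batch_af=batch_af,
        pooled_af=pooled_af,
        batch_rsq=batch_rsq,
        duplicated_ids=duplicated_ids,
        vcf_paths=vcf_paths,
        info_paths=info_paths,
    )
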