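"""Variant selection: build the merge plan from per-batch info tables.

The union of variant keys across all batches is classified by two rules,
applied in a fixed order so the recorded exclusion reason is deterministic:

1. *missingness* — a variant absent from more than ``missing_allowance``
   batches is excluded (reason ``too-many-missing``);
2. *quality threshold* — otherwise, a variant whose Fisher-combined
   R-squared is present and below ``rsq_threshold`` is excluded (reason
   ``below-threshold``). A variant with no reported quality in any batch
   has no combined value and cannot fail the threshold.

Retained variants, ordered by (pos, ref, alt) within the chromosome, form
the :class:`MergePlan` that drives the streaming merge. Both retained and
excluded variants get full combined statistics so the audit tables are
informative either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import DuplicateVariantError, FormatError
from .formats import BatchInfoRecord, InfoTable, VariantKey
from .stats import (
    CombinedInfoRecord,
    ExclusionReason,
    combine_af,
    combine_genotyped_status,
    combine_rsq,
)

__all__ = ["MergeConfig", "PlannedVariant", "MergePlan", "build_merge_plan", "write_info_outputs"]


@dataclass
class MergeConfig:
    """User-facing parameters of one merge run."""

    vcf_paths: list[Path]
    info_paths: list[Path | None] | None = None
    missing_allowance: int = 0
    rsq_threshold: float = 0.0
    out_prefix: str = "merged"
    weight_mode: str = "n"  # "n" or "n-3"
    threads: int = 1

    def __post_init__(self) -> None:
        self.vcf_paths = [Path(p) for p in self.vcf_paths]
        n = len(self.vcf_paths)
        if n < 1:
            raise ValueError("at least one input batch is required")
        if not 0 <= self.missing_allowance <= max(n - 1, 0):
            raise ValueError(
                f"missing_allowance must be in [0, {n - 1}], got {self.missing_allowance}"
            )
        if not 0.0 <= self.rsq_threshold <= 1.0:
            raise ValueError("rsq_threshold must be in [0, 1]")
        if self.weight_mode not in ("n", "n-3"):
            raise ValueError("weight_mode must be 'n' or 'n-3'")


@dataclass
class PlannedVariant:
    key: VariantKey
    presence: list[bool]
    combined: CombinedInfoRecord
    per_batch: list[BatchInfoRecord | None] = field(default_factory=list)


@dataclass
class MergePlan:
    """Ordered retained variants with per-batch presence vectors."""

    variants: list[PlannedVariant]
    n_batches: int

    def __len__(self) -> int:
        return len(self.variants)


def _batch_weight(n_samples: int, weight_mode: str) -> float:
    if weight_mode == "n-3":
        w = n_samples - 3
        if w <= 0:
            raise ValueError(
                f"weight_mode 'n-3' needs batches of more than 3 samples (got n={n_samples})"
            )
        return float(w)
    return float(n_samples)


def combine_records(
    key: VariantKey,
    per_batch: Sequence[BatchInfoRecord | None],
    weight_mode: str = "n",
) -> CombinedInfoRecord:
    """Compute the cross-batch summary for one variant.

    ``per_batch`` holds one entry per batch, ``None`` where the variant is
    absent. Absent batches are not counted in any statistic; present
    batches with a placeholder Rsq still count toward AF/MAF and status.
    """
    present = [r for r in per_batch if r is not None]
    if not present:
        raise ValueError(f"variant {key} present in no batch")
    af_pairs = [(r.af, _batch_weight(r.n_samples, weight_mode)) for r in present]
    maf_pairs = [(r.maf, _batch_weight(r.n_samples, weight_mode)) for r in present]
    rsq_pairs = [
        (r.rsq, _batch_weight(r.n_samples, weight_mode))
        for r in present
        if r.rsq is not None
    ]
    af_w, af_min, af_max = combine_af(af_pairs)  # type: ignore[misc]
    maf_w, maf_min, maf_max = combine_af(maf_pairs)  # type: ignore[misc]
    rsq_combined = combine_rsq(rsq_pairs)
    rsq_vals = [r.rsq for r in present if r.rsq is not None]
    return CombinedInfoRecord(
        key=key,
        rsq_combined=rsq_combined,
        rsq_min=min(rsq_vals) if rsq_vals else None,
        rsq_max=max(rsq_vals) if rsq_vals else None,
        af_weighted=af_w,
        af_min=af_min,
        af_max=af_max,
        maf_weighted=maf_w,
        maf_min=maf_min,
        maf_max=maf_max,
        genotyped_status=combine_genotyped_status([r.genotyped for r in present]),
        n_missing_batches=sum(1 for r in per_batch if r is None),
        n_effective=sum(r.n_samples for r in present),
    )


def build_merge_plan(
    tables: Sequence[InfoTable], config: MergeConfig
) -> tuple[MergePlan, list[PlannedVariant]]:
    """Union variant keys across batches and classify each as retained or excluded.

    Returns the plan (retained variants in (pos, ref, alt) order) and the
    excluded variants, each carrying its combined statistics and the first
    rule it violated (missingness is checked before the quality threshold).
    """
    n_batches = len(tables)
    per_key: dict[VariantKey, list[BatchInfoRecord | None]] = {}
    for b, table in enumerate(tables):
        for rec in table:
            slot = per_key.setdefault(rec.key, [None] * n_batches)
            if slot[b] is not None:
                raise DuplicateVariantError(
                    f"batch {b}: variant {rec.key} appears twice in its info table"
                )
            slot[b] = rec
    retained: list[PlannedVariant] = []
    excluded: list[PlannedVariant] = []
    for key in sorted(per_key, key=lambda k: (k.pos, k.ref, k.alt)):
        slots = per_key[key]
        combined = combine_records(key, slots, config.weight_mode)
        pv = PlannedVariant(
            key=key,
            presence=[s is not None for s in slots],
            combined=combined,
            per_batch=list(slots),
        )
        n_absent = combined.n_missing_batches
        if n_absent > config.missing_allowance:
            combined.retained = False
            combined.exclusion_reason = ExclusionReason.TOO_MANY_MISSING
            excluded.append(pv)
        elif (
            combined.rsq_combined is not None
            and combined.rsq_combined < config.rsq_threshold
        ):
            combined.retained = False
            combined.exclusion_reason = ExclusionReason.BELOW_THRESHOLD
            excluded.append(pv)
        else:
            retained.append(pv)
    return MergePlan(variants=retained, n_batches=n_batches), excluded


def _fmt(x: float | None) -> str:
    return "." if x is None else f"{x:.6g}"


_COMBINED_COLS = [
    "SNP", "REF", "ALT", "Genotyped",
    "Rsq_combined", "Rsq_min", "Rsq_max",
    "ALT_Frq_weighted", "ALT_Frq_min", "ALT_Frq_max",
    "MAF_weighted", "MAF_min", "MAF_max",
    "Missing_batches",
]


def write_info_outputs(
    plan: MergePlan,
    excluded: Sequence[PlannedVariant],
    prefix: str | Path,
    batch_labels: Sequence[str] | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>_retained.info.txt`` and ``<prefix>_excluded.info.txt``.

    Both are tab-delimited with combined columns followed by per-batch
    AF/MAF/Rsq/Genotyped columns suffixed by batch label; absent cells are
    '.'. The excluded table adds an ``Exclusion_reason`` column.
    """
    prefix = str(prefix)
    if batch_labels is None:
        batch_labels = [f"batch{i}" for i in range(plan.n_batches)]
    if len(batch_labels) != plan.n_batches:
        raise FormatError("one batch label per batch is required")
    per_batch_cols: list[str] = []
    for label in batch_labels:
        per_batch_cols += [f"ALT_Frq_{label}", f"MAF_{label}", f"Rsq_{label}", f"Genotyped_{label}"]

    def rows(variants: Sequence[PlannedVariant], with_reason: bool):
        for pv in variants:
            c = pv.combined
            row = [
                str(pv.key), pv.key.ref, pv.key.alt, c.genotyped_status.value,
                _fmt(c.rsq_combined), _fmt(c.rsq_min), _fmt(c.rsq_max),
                _fmt(c.af_weighted), _fmt(c.af_min), _fmt(c.af_max),
                _fmt(c.maf_weighted), _fmt(c.maf_min), _fmt(c.maf_max),
                str(c.n_missing_batches),
            ]
            for rec in pv.per_batch:
                if rec is None:
                    row += [".", ".", ".", "."]
                else:
                    row += [
                        _fmt(rec.af), _fmt(rec.maf), _fmt(rec.rsq),
                        "Genotyped" if rec.genotyped else "Imputed",
                    ]
            if with_reason:
                row.append(c.exclusion_reason.value if c.exclusion_reason else ".")
            yield row

    retained_path = Path(f"{prefix}_retained.info.txt")
    excluded_path = Path(f"{prefix}_excluded.info.txt")
    with open(retained_path, "w") as fh:
        fh.write("\t".join(_COMBINED_COLS + per_batch_cols) + "\n")
        for row in rows(plan.variants, with_reason=False):
            fh.write("\t".join(row) + "\n")
    with open(excluded_path, "w") as fh:
        fh.write("\t".join(_COMBINED_COLS + per_batch_cols + ["Exclusion_reason"]) + "\n")
        for row in rows(excluded, with_reason=True):
            fh.write("\t".join(row) + "\n")
    return retained_path, excluded_path
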