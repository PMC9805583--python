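"""The streaming merge: synchronized single-pass scan of all batch VCFs.

All input files are opened simultaneously and consumed strictly forward —
each line is read at most once and the scan never rewinds. For every
retained variant (in position order) each batch's stream is advanced to
that position; records at one position are buffered so allele order within
a position may differ between the plan and a file. A variant announced by
a batch's info table but not found in its VCF before the scan passes its
position is a desynchronization error.

Sample columns are concatenated in batch order. Sample IDs duplicated
across batches are kept as distinct columns: the first occurrence keeps
the original ID and later occurrences get a ``:2``, ``:3``, ... suffix,
with every shared ID listed in ``duplicates.txt``. For a retained variant
absent from some batch, that batch's columns are filled with ``.|.`` in
the GT slot and ``.`` in every other FORMAT slot.

Only compression and decompression may use extra threads; the merge logic
itself is a deterministic single scan, so the decompressed output bytes
are identical for any thread count.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from . import __version__
from .errors import DesyncError, FormatError, MergeError
from .formats import (
    BatchInfoRecord,
    InfoTable,
    MergedVcfWriter,
    VariantKey,
    provenance_line,
    read_info_table,
    read_vcf_header,
    read_vcf_meta_lines,
    stream_vcf_records,
)
from .plan import MergeConfig, MergePlan, PlannedVariant, build_merge_plan, write_info_outputs
from .stats import CombinedInfoRecord, ExclusionReason

__all__ = [
    "SampleRegistry",
    "resolve_duplicates",
    "missing_fill",
    "merge_variant_row",
    "merge_batches",
    "MergeSummary",
]

_RSQ_INFO_KEYS = ("R2", "Rsq", "DR2")
_AF_INFO_KEYS = ("AF", "ALT_Frq", "ALT_frq")
_MAF_INFO_KEYS = ("MAF",)


@dataclass
class SampleRegistry:
    """Output sample-column layout across batches.

    ``output_ids`` concatenates batches in batch order with within-batch
    order preserved; IDs are globally unique after duplicate renaming.
    ``duplicates`` maps each original ID shared by several batches to its
    (batch index, output ID) occurrences.
    """

    per_batch_ids: list[list[str]]
    output_ids: list[str]
    duplicates: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.output_ids)


def resolve_duplicates(per_batch_ids: Sequence[Sequence[str]]) -> SampleRegistry:
    """Assign globally unique output IDs, renaming cross-batch duplicates.

    The first occurrence (lowest batch index) keeps its original ID; the
    j-th later occurrence becomes ``<ID>:<j+1>``. Should a renamed ID
    collide with a pre-existing one, further ``.k`` suffixes are added
    until unique, so renaming always succeeds.
    """
    used: set[str] = set()
    occurrences: dict[str, list[tuple[int, str]]] = {}
    output_ids: list[str] = []
    for b, ids in enumerate(per_batch_ids):
        for sid in ids:
            prior = occurrences.get(sid)
            if prior is None:
                out_id = sid
                if out_id in used:  # collides with someone else's renamed ID
                    k = 2
                    while f"{out_id}.{k}" in used:
                        k += 1
                    out_id = f"{out_id}.{k}"
            else:
                out_id = f"{sid}:{len(prior) + 1}"
                k = 2
                while out_id in used:
                    out_id = f"{sid}:{len(prior) + 1}.{k}"
                    k += 1
            used.add(out_id)
            occurrences.setdefault(sid, []).append((b, out_id))
            output_ids.append(out_id)
    duplicates = {sid: occ for sid, occ in occurrences.items() if len(occ) > 1}
    return SampleRegistry(
        per_batch_ids=[list(ids) for ids in per_batch_ids],
        output_ids=output_ids,
        duplicates=duplicates,
    )


def missing_fill(format_spec: str, n_samples: int) -> list[str]:
    """Genotype-column fill for a batch lacking the variant.

    The GT slot is ``.|.`` and every other FORMAT key is ``.``, e.g.
    ``GT:DS:GP`` -> ``.|.:.:.``; one such value per sample.
    """
    keys = format_spec.split(":")
    if not keys or keys[0] != "GT":
        raise FormatError(f"FORMAT {format_spec!r} does not begin with GT")
    cell = ":".join([".|."] + ["."] * (len(keys) - 1))
    return [cell] * n_samples


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _rewrite_info(info: str, combined: CombinedInfoRecord) -> str:
    """Replace AF/MAF/quality tokens with combined values; append status.

    Unrecognized tokens and token order are preserved from the donor row.
    Combined values are inserted even when the donor lacked the key; a
    missing combined quality renders as '.'.
    """
    tokens = [] if info == "." else info.split(";")
    out: list[str] = []
    seen = {"af": False, "maf": False, "rsq": False}
    rsq_str = "." if combined.rsq_combined is None else _fmt(combined.rsq_combined)
    for token in tokens:
        key = token.split("=", 1)[0] if "=" in token else token
        if key in _AF_INFO_KEYS and not seen["af"]:
            out.append(f"{key}={_fmt(combined.af_weighted)}")
            seen["af"] = True
        elif key in _MAF_INFO_KEYS and not seen["maf"]:
            out.append(f"{key}={_fmt(combined.maf_weighted)}")
            seen["maf"] = True
        elif key in _RSQ_INFO_KEYS and not seen["rsq"]:
            out.append(f"{key}={rsq_str}")
            seen["rsq"] = True
        else:
            out.append(token)
    if not seen["af"]:
        out.append(f"AF={_fmt(combined.af_weighted)}")
    if not seen["maf"]:
        out.append(f"MAF={_fmt(combined.maf_weighted)}")
    if not seen["rsq"] and combined.rsq_combined is not None:
        out.append(f"R2={rsq_str}")
    out.append(f"TYPED_STATUS={combined.genotyped_status.value}")
    return ";".join(out)


def merge_variant_row(
    key: VariantKey,
    per_batch_rows: Sequence[Sequence[str] | None],
    combined: CombinedInfoRecord,
    registry: SampleRegistry,
) -> list[str]:
    """Splice one merged VCF data row from the per-batch raw rows.

    CHROM..FILTER, FORMAT and unrecognized INFO tokens come from the first
    present batch; genotype columns are concatenated in batch order with
    absent batches filled by :func:`missing_fill`. A present batch whose
    FORMAT differs from the donor's is a merge error — subfield reordering
    would silently corrupt dosages.
    """
    donor = next((r for r in per_batch_rows if r is not None), None)
    if donor is None:
        raise MergeError(f"variant {key}: no batch supplied a row")
    fmt = donor[8]
    row = list(donor[:7])
    row.append(_rewrite_info(donor[7], combined))
    row.append(fmt)
    for b, batch_row in enumerate(per_batch_rows):
        n = len(registry.per_batch_ids[b])
        if batch_row is None:
            row.extend(missing_fill(fmt, n))
        else:
            if batch_row[8] != fmt:
                raise MergeError(
                    f"variant {key}: batch {b} FORMAT {batch_row[8]!r} differs from {fmt!r}"
                )
            gts = batch_row[9:]
            if len(gts) != n:
                raise FormatError(
                    f"variant {key}: batch {b} row has {len(gts)} genotype columns, "
                    f"header has {n}"
                )
            row.extend(gts)
    return row


class _BatchScanner:
    """Forward-only scanner over one batch VCF with a same-position buffer."""

    def __init__(self, path: Path) -> None:
        self.path = path
        self._it: Iterator[tuple[VariantKey, list[str]]] = stream_vcf_records(path)
        self._buffer: dict[tuple[str, str], list[str]] = {}
        self._buffer_pos: int | None = None
        self._pending: tuple[VariantKey, list[str]] | None = None
        self.n_records_read = 0
        self.exhausted = False

    def _next_record(self) -> tuple[VariantKey, list[str]] | None:
        if self._pending is not None:
            rec, self._pending = self._pending, None
            return rec
        try:
            rec = next(self._it)
        except StopIteration:
            self.exhausted = True
            return None
        self.n_records_read += 1
        return rec

    def fetch(self, target: VariantKey) -> list[str] | None:
        """Advance to ``target.pos`` and return the row for ``target`` if present.

        Rows before the target position are discarded (they were excluded
        by the plan); rows at the target position are buffered so multiple
        alleles at one position can be fetched in any order.
        """
        if self._buffer_pos is not None and self._buffer_pos == target.pos:
            return self._buffer.get((target.ref, target.alt))
        if self._buffer_pos is not None and self._buffer_pos > target.pos:
            return None
        self._buffer.clear()
        self._buffer_pos = None
        while True:
            rec = self._next_record()
            if rec is None:
                return None
            key, fields = rec
            if key.pos < target.pos:
                continue
            if key.pos > target.pos:
                self._pending = rec
                return None
            # key.pos == target.pos: buffer the whole position
            self._buffer_pos = target.pos
            self._buffer[(key.ref, key.alt)] = fields
            while True:
                nxt = self._next_record()
                if nxt is None:
                    break
                if nxt[0].pos != target.pos:
                    self._pending = nxt
                    break
                self._buffer[(nxt[0].ref, nxt[0].alt)] = nxt[1]
            return self._buffer.get((target.ref, target.alt))

    def drain(self) -> int:
        """Consume the remainder of the stream; return total records read."""
        if self._pending is not None:
            self._pending = None
        for _ in self._it:
            self.n_records_read += 1
        return self.n_records_read


@dataclass
class MergeSummary:
    """Exact counts from one merge run."""

    n_retained: int
    n_excluded_missing: int
    n_excluded_threshold: int
    n_samples: int
    n_duplicates: int
    outputs: dict[str, Path] = field(default_factory=dict)


def _derive_info_path(vcf_path: Path) -> Path:
    name = vcf_path.name
    if name.endswith(".vcf.gz"):
        root = name[: -len(".vcf.gz")]
    elif name.endswith(".vcf"):
        root = name[: -len(".vcf")]
    else:
        root = name
    return vcf_path.with_name(root + ".info.gz")


def merge_batches(config: MergeConfig) -> MergeSummary:
    """Run the full merge: plan, info outputs, streamed VCF, duplicates, log.

    Writes ``<prefix>.vcf.gz`` (block-gzipped), ``<prefix>_retained.info.txt``,
    ``<prefix>_excluded.info.txt``, ``duplicates.txt`` next to the prefix and
    ``<prefix>.log``. Returns exact counts. On any fatal error the partial
    VCF output is removed.
    """
    info_paths: list[Path] = []
    given = config.info_paths or [None] * len(config.vcf_paths)
    for vcf_path, ip in zip(config.vcf_paths, given):
        info_paths.append(Path(ip) if ip is not None else _derive_info_path(vcf_path))

    batches = []
    tables: list[InfoTable] = []
    for b, (vcf_path, info_path) in enumerate(zip(config.vcf_paths, info_paths)):
        bf = read_vcf_header(vcf_path)
        bf.batch_index = b
        bf.info_path = info_path
        batches.append(bf)
        tables.append(read_info_table(info_path, n_samples=bf.n_samples))

    plan, excluded = build_merge_plan(tables, config)
    registry = resolve_duplicates([bf.sample_ids for bf in batches])

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    labels = [_label(p) for p in config.vcf_paths]
    if len(set(labels)) != len(labels):
        labels = [f"batch{i}" for i in range(len(labels))]
    retained_path, excluded_path = write_info_outputs(plan, excluded, prefix, labels)

    dup_path = prefix.parent / "duplicates.txt"
    with open(dup_path, "w") as fh:
        fh.write("ID\tBatch\tOutput_ID\n")
        for sid in sorted(registry.duplicates):
            for b, out_id in registry.duplicates[sid]:
                fh.write(f"{sid}\t{b}\t{out_id}\n")

    meta = read_vcf_meta_lines(config.vcf_paths[0])
    meta.append(
        provenance_line(
            "vcfmerge",
            len(batches),
            {
                "version": __version__,
                "missing": config.missing_allowance,
                "rsq_threshold": config.rsq_threshold,
                "weight_mode": config.weight_mode,
            },
        )
    )
    chrom_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header_lines = meta + ["\t".join(chrom_cols + registry.output_ids)]

    vcf_out = Path(f"{prefix}.vcf.gz")
    writer = MergedVcfWriter(
        vcf_out, header_lines, 9 + registry.n_samples, threads=config.threads
    )
    scanners = [_BatchScanner(p) for p in config.vcf_paths]
    try:
        for pv in plan.variants:
            per_batch_rows: list[list[str] | None] = []
            for b, scanner in enumerate(scanners):
                if not pv.presence[b]:
                    per_batch_rows.append(None)
                    continue
                row = scanner.fetch(pv.key)
                if row is None:
                    raise DesyncError(
                        f"batch {b} ({scanner.path}): variant {pv.key} announced by the "
                        "info table was not found in the VCF at its position"
                    )
                per_batch_rows.append(row)
            writer.write_row(merge_variant_row(pv.key, per_batch_rows, pv.combined, registry))
        for b, scanner in enumerate(scanners):
            n_vcf = scanner.drain()
            if n_vcf != len(tables[b]):
                raise FormatError(
                    f"batch {b} ({scanner.path}): VCF has {n_vcf} records but its info "
                    f"table has {len(tables[b])} rows"
                )
    except Exception:
        writer.abort()
        raise
    writer.close()

    n_missing = sum(
        1 for pv in excluded if pv.combined.exclusion_reason is ExclusionReason.TOO_MANY_MISSING
    )
    n_thresh = len(excluded) - n_missing
    summary = MergeSummary(
        n_retained=len(plan.variants),
        n_excluded_missing=n_missing,
        n_excluded_threshold=n_thresh,
        n_samples=registry.n_samples,
        n_duplicates=len(registry.duplicates),
        outputs={
            "vcf": vcf_out,
            "retained_info": retained_path,
            "excluded_info": excluded_path,
            "duplicates": dup_path,
            "log": Path(f"{prefix}.log"),
        },
    )
    _write_log(summary, config, batches, tables, registry)
    return summary


def _label(path: Path) -> str:
    name = path.name
    for suffix in (".vcf.gz", ".vcf"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def _write_log(summary, config, batches, tables, registry) -> None:
    with open(summary.outputs["log"], "w") as fh:
        fh.write(f"vcfmerge {__version__} — merge log\n")
        fh.write(f"date: {datetime.datetime.now().isoformat(timespec='seconds')}\n\n")
        fh.write("parameters:\n")
        fh.write(f"  missing_allowance: {config.missing_allowance}\n")
        fh.write(f"  rsq_threshold: {config.rsq_threshold}\n")
        fh.write(f"  weight_mode: {config.weight_mode}\n")
        fh.write(f"  threads: {config.threads}\n\n")
        fh.write("batches:\n")
        for bf, table in zip(batches, tables):
            dialect = ",".join(f"{k}={v}" for k, v in table.column_dialect.items())
            fh.write(
                f"  [{bf.batch_index}] {bf.vcf_path} ({bf.n_samples} samples, "
                f"{len(table)} variants; info dialect: {dialect})\n"
            )
        fh.write("\nsummary:\n")
        fh.write(f"  retained variants: {summary.n_retained}\n")
        fh.write(f"  excluded (too-many-missing): {summary.n_excluded_missing}\n")
        fh.write(f"  excluded (below-threshold): {summary.n_excluded_threshold}\n")
        fh.write(f"  output samples: {summary.n_samples}\n")
        fh.write(f"  duplicated sample IDs: {summary.n_duplicates}\n")
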