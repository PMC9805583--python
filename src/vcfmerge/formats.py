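"""File formats and the variant/record data model.

Reads and writes the concrete formats the merger touches:

* genotype files: VCF 4.x, gzip- or bgzip-compressed, one chromosome per
  file, variants sorted by position;
* info tables: Minimac3/4-style tab-delimited ``*.info.gz`` files carrying
  per-variant ALT frequency, MAF, imputation R-squared and genotyped status;
* the merged output VCF, written block-gzipped (BGZF) so it can be indexed
  downstream.

Variant identity throughout the package is the exact tuple
``(chrom, pos, ref, alt)``; multiallelic sites already split into per-ALT
rows by imputation servers stay separate records, and no allele
normalization or liftover is attempted — the merge is byte-faithful.
"""

from __future__ import annotations

import gzip
import io
import os
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pysam

from .errors import FormatError, InputError, SortOrderError

__all__ = [
    "VariantKey",
    "BatchInfoRecord",
    "BatchFile",
    "InfoTable",
    "read_info_table",
    "read_vcf_header",
    "stream_vcf_records",
    "write_merged_vcf",
    "MergedVcfWriter",
    "open_text",
]

#: tokens that Minimac-family tools emit for an unavailable Rsq
MISSING_TOKENS = frozenset({"-", ".", "", "NA", "nan"})

# Column-name synonyms across TOPMed / Michigan server generations.
# Matched case-insensitively; first synonym found in the header wins.
_DIALECTS = {
    "snp": ("SNP", "ID", "variant_id"),
    "ref": ("REF(0)", "REF"),
    "alt": ("ALT(1)", "ALT"),
    "af": ("ALT_Frq", "AF", "ALT_frq"),
    "maf": ("MAF",),
    "rsq": ("Rsq", "R2"),
    "genotyped": ("Genotyped", "TYPED"),
}


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one alternate-allele record.

    Sort order is (chrom, pos, ref, alt); within a single chromosome this
    reduces to (pos, ref, alt), the tie-break used everywhere in the merge.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class BatchInfoRecord:
    """One variant's per-batch statistics from an info table."""

    key: VariantKey
    af: float
    maf: float
    rsq: float | None
    genotyped: bool
    n_samples: int


@dataclass
class BatchFile:
    """One input batch: paths, sample IDs and position in batch order."""

    vcf_path: Path
    info_path: Path | None
    sample_ids: list[str]
    batch_index: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class InfoTable:
    """Per-batch info records in file order plus the detected dialect."""

    records: list[BatchInfoRecord]
    column_dialect: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BatchInfoRecord]:
        return iter(self.records)


def open_text(path: str | os.PathLike[str], mode: str = "rt") -> IO[str]:
    """Open plain, gzip- or bgzip-compressed text transparently.

    BGZF is a conforming multi-member gzip stream, so :mod:`gzip` reads
    both compressed flavours; plain text is detected by magic bytes.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _parse_key_from_id(snp: str, ref: str, alt: str, lineno: int, path: Path) -> VariantKey:
    """Build a VariantKey from a Minimac variant ID like chr1:100:A:G.

    Falls back to chrom:pos when the ID omits alleles, taking REF/ALT from
    their dedicated columns.
    """
    parts = snp.split(":")
    if len(parts) < 2:
        raise FormatError(
            f"{path}: line {lineno}: variant ID {snp!r} is not chrom:pos[:ref:alt]"
        )
    try:
        pos = int(parts[1])
    except ValueError as exc:
        raise FormatError(
            f"{path}: line {lineno}: non-integer position in variant ID {snp!r}"
        ) from exc
    return VariantKey(chrom=parts[0], pos=pos, ref=ref, alt=alt)


def _detect_dialect(header_cols: Sequence[str], path: Path) -> dict[str, int]:
    lowered = [c.strip().lower() for c in header_cols]
    mapping: dict[str, int] = {}
    for field_name, synonyms in _DIALECTS.items():
        for syn in synonyms:
            try:
                mapping[field_name] = lowered.index(syn.lower())
                break
            except ValueError:
                continue
        else:
            raise FormatError(
                f"{path}: info table header lacks a recognised "
                f"{'/'.join(synonyms)} column"
            )
    return mapping


def _parse_float(token: str, what: str, lineno: int, path: Path) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"{path}: line {lineno}: unparsable {what} value {token!r}") from exc


def read_info_table(path: str | os.PathLike[str], n_samples: int) -> InfoTable:
    """Read a Minimac-dialect info table into one record per data row.

    Column names are matched against known synonym sets (Rsq/R2,
    ALT_Frq/AF, Genotyped/TYPED, ...) case-insensitively. Placeholder Rsq
    tokens ('-', '.', empty) become ``None``. AF, MAF and Rsq are bounds-
    checked; violations report the offending row number.
    """
    path = Path(path)
    records: list[BatchInfoRecord] = []
    with open_text(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty info file (no header row)")
        cols = header.rstrip("\n").split("\t")
        idx = _detect_dialect(cols, path)
        dialect = {name: cols[i] for name, i in idx.items()}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            snp = fields[idx["snp"]]
            ref = fields[idx["ref"]]
            alt = fields[idx["alt"]]
            key = _parse_key_from_id(snp, ref, alt, lineno, path)
            af = _parse_float(fields[idx["af"]], "AF", lineno, path)
            maf = _parse_float(fields[idx["maf"]], "MAF", lineno, path)
            rsq_token = fields[idx["rsq"]].strip()
            rsq: float | None
            if rsq_token in MISSING_TOKENS:
                rsq = None
            else:
                rsq = _parse_float(rsq_token, "Rsq", lineno, path)
                if not 0.0 <= rsq <= 1.0:
                    raise FormatError(f"{path}: line {lineno}: Rsq {rsq} outside [0,1]")
            if not 0.0 <= af <= 1.0:
                raise FormatError(f"{path}: line {lineno}: AF {af} outside [0,1]")
            if not 0.0 <= maf <= 0.5 + 1e-9:
                raise FormatError(f"{path}: line {lineno}: MAF {maf} outside [0,0.5]")
            genotyped_token = fields[idx["genotyped"]].strip().lower()
            genotyped = genotyped_token in {"genotyped", "typed", "true", "1", "yes"}
            records.append(
                BatchInfoRecord(
                    key=key, af=af, maf=maf, rsq=rsq,
                    genotyped=genotyped, n_samples=n_samples,
                )
            )
    return InfoTable(records=records, column_dialect=dialect)


def read_vcf_header(path: str | os.PathLike[str]) -> BatchFile:
    """Parse the VCF header and return sample IDs in column order.

    Requires ``##fileformat=VCF`` meta lines followed by one ``#CHROM``
    header line; duplicate sample IDs *within* one file are a format error
    (cross-batch duplicates are handled later by the sample registry).
    """
    path = Path(path)
    with open_text(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{path}: does not start with a ##fileformat=VCF meta line")
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 8:
                    raise FormatError(f"{path}: malformed #CHROM header line")
                samples = cols[9:] if len(cols) > 9 else []
                seen: set[str] = set()
                for s in samples:
                    if s in seen:
                        raise FormatError(f"{path}: duplicate sample ID {s!r} within one file")
                    seen.add(s)
                return BatchFile(vcf_path=path, info_path=None, sample_ids=samples)
            raise FormatError(f"{path}: data line encountered before #CHROM header")
    raise FormatError(f"{path}: no #CHROM header line found")


def read_vcf_meta_lines(path: str | os.PathLike[str]) -> list[str]:
    """Return the ``##`` meta lines of a VCF (without trailing newlines)."""
    meta: list[str] = []
    with open_text(path) as fh:
        for line in fh:
            if line.startswith("##"):
                meta.append(line.rstrip("\n"))
            else:
                break
    return meta


def stream_vcf_records(
    path: str | os.PathLike[str],
) -> Iterator[tuple[VariantKey, list[str]]]:
    """Yield ``(VariantKey, raw fields)`` for each data row, in file order.

    The file is streamed, never loaded whole. Each yielded field list is the
    unmodified tab-split row (all columns, FORMAT and genotypes included) so
    the merge can splice text byte-faithfully. A decrease in position
    relative to the previous record violates the sortedness contract of the
    inputs and raises :class:`SortOrderError` — sorting is never repaired.
    """
    path = Path(path)
    prev_pos: int | None = None
    with open_text(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}: line {lineno}: fewer than 8 VCF columns")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer POS {fields[1]!r}") from exc
            if prev_pos is not None and pos < prev_pos:
                raise SortOrderError(
                    f"{path}: line {lineno}: position {pos} decreases after {prev_pos}; "
                    "input VCFs must be sorted by position"
                )
            prev_pos = pos
            key = VariantKey(chrom=fields[0], pos=pos, ref=fields[3], alt=fields[4])
            yield key, fields


class MergedVcfWriter:
    """Streaming BGZF writer for the merged VCF.

    Validates every data row against the header's column count and removes
    the partial output file if the merge aborts, so a truncated bgzip VCF
    never survives a failed run. With ``threads > 1`` compression is piped
    through the ``bgzip`` command-line tool; the decompressed byte content
    is identical for any thread count.
    """

    def __init__(
        self,
        path: str | os.PathLike[str],
        header_lines: Sequence[str],
        n_columns: int,
        threads: int = 1,
    ) -> None:
        self.path = Path(path)
        self.n_columns = n_columns
        self.n_records = 0
        self._proc: subprocess.Popen[bytes] | None = None
        if threads > 1:
            out = open(self.path, "wb")
            self._proc = subprocess.Popen(
                ["bgzip", "-c", f"-@{threads}"],
                stdin=subprocess.PIPE, stdout=out,
            )
            out.close()
            assert self._proc.stdin is not None
            self._fh: IO[str] = io.TextIOWrapper(self._proc.stdin, encoding="ascii")
        else:
            self._fh = io.TextIOWrapper(
                pysam.BGZFile(str(self.path), "wb"), encoding="ascii"
            )
        for line in header_lines:
            self._fh.write(line + "\n")

    def write_row(self, fields: Sequence[str]) -> None:
        if len(fields) != self.n_columns:
            self.abort()
            raise MergeInternalError(
                f"merged row has {len(fields)} columns, header implies {self.n_columns}"
            )
        self._fh.write("\t".join(fields) + "\n")
        self.n_records += 1

    def close(self) -> None:
        self._fh.close()
        if self._proc is not None:
            self._proc.wait()
            if self._proc.returncode != 0:
                raise InputError("bgzip compression subprocess failed")

    def abort(self) -> None:
        """Close and delete the partial output."""
        try:
            self._fh.close()
        except Exception:
            pass
        if self._proc is not None:
            self._proc.wait()
        if self.path.exists():
            self.path.unlink()


class MergeInternalError(FormatError):
    """Header/row column-count mismatch detected while writing output."""


def write_merged_vcf(
    header_lines: Sequence[str],
    records: Iterable[Sequence[str]],
    path: str | os.PathLike[str],
    threads: int = 1,
) -> int:
    """Write header + rows to a block-gzipped VCF; returns the row count.

    ``header_lines`` must include the final ``#CHROM`` line; its column
    count is enforced on every record. On a column mismatch the partial
    output is removed and an error is raised.
    """
    chrom_line = header_lines[-1]
    n_columns = len(chrom_line.split("\t"))
    writer = MergedVcfWriter(path, header_lines, n_columns, threads=threads)
    try:
        for rec in records:
            writer.write_row(rec)
    except MergeInternalError:
        raise
    except Exception:
        writer.abort()
        raise
    writer.close()
    return writer.n_records


def provenance_line(tool: str, n_batches: int, params: dict[str, object]) -> str:
    """A ``##`` meta line recording tool name, batch count and parameters."""
    kv = ",".join(f"{k}={v}" for k, v in params.items())
    return f"##{tool}_merge=<batches={n_batches},{kv}>"
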