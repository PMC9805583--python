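"""Derive a Minimac-dialect info table from VCF INFO annotations.

Imputation servers ship a companion ``*.info.gz`` next to each VCF; other
pipelines only carry AF / MAF / R2 / TYPED annotations in the VCF INFO
column. This step reshapes those annotations into the info-table dialect
the planner reads — nothing is recomputed from dosages.

Accepted INFO keys (first match wins): quality R2/Rsq/DR2; frequency
AF/ALT_Frq; MAF (derived as min(AF, 1-AF) when absent); genotyped status
from a TYPED or GENOTYPED flag (or TYPED=.../Genotyped=... token), else
imputed. Numbers are re-emitted with up to 6 significant digits.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

from .errors import FormatError
from .formats import (
    BatchInfoRecord,
    InfoTable,
    VariantKey,
    read_vcf_header,
    stream_vcf_records,
)

__all__ = ["build_info_from_vcf"]

_RSQ_KEYS = ("R2", "Rsq", "DR2")
_AF_KEYS = ("AF", "ALT_Frq", "ALT_frq")
_MAF_KEYS = ("MAF",)
_TYPED_FLAGS = ("TYPED", "GENOTYPED", "TYPED_ONLY")

_HEADER = "SNP\tREF(0)\tALT(1)\tALT_Frq\tMAF\tAvgCall\tRsq\tGenotyped\n"


def _parse_info(info: str) -> tuple[dict[str, str], list[str]]:
    kv: dict[str, str] = {}
    flags: list[str] = []
    if info == ".":
        return kv, flags
    for token in info.split(";"):
        if "=" in token:
            k, v = token.split("=", 1)
            kv.setdefault(k, v)
        elif token:
            flags.append(token)
    return kv, flags


def _first(kv: dict[str, str], keys: tuple[str, ...]) -> str | None:
    for k in keys:
        if k in kv:
            return kv[k]
    return None


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def build_info_from_vcf(vcf_path: str | os.PathLike[str], info_out: str | os.PathLike[str]) -> InfoTable:
    """Write an info table with one row per VCF record, in VCF order.

    Variant IDs are rendered ``chrom:pos:ref:alt``. A row lacking AF, or
    lacking a quality key while not flagged genotyped, is a format error
    naming the offending record.
    """
    vcf_path = Path(vcf_path)
    info_out = Path(info_out)
    batch = read_vcf_header(vcf_path)
    n = batch.n_samples
    records: list[BatchInfoRecord] = []
    with gzip.open(info_out, "wt") as out:
        out.write(_HEADER)
        for i, (key, fields) in enumerate(stream_vcf_records(vcf_path), start=1):
            kv, flags = _parse_info(fields[7])
            af_token = _first(kv, _AF_KEYS)
            if af_token is None:
                raise FormatError(f"{vcf_path}: record {i} ({key}): INFO lacks an AF key")
            af = float(af_token)
            maf_token = _first(kv, _MAF_KEYS)
            maf = float(maf_token) if maf_token is not None else min(af, 1.0 - af)
            genotyped = any(f.upper() in _TYPED_FLAGS for f in flags) or any(
                k.upper() in _TYPED_FLAGS for k in kv
            )
            rsq_token = _first(kv, _RSQ_KEYS)
            rsq: float | None
            if rsq_token is None or rsq_token in ("-", "."):
                if not genotyped and rsq_token is None:
                    raise FormatError(
                        f"{vcf_path}: record {i} ({key}): INFO lacks a quality key "
                        "and the variant is not flagged genotyped"
                    )
                rsq = None
            else:
                rsq = float(rsq_token)
            out.write(
                "\t".join(
                    [
                        str(key), key.ref, key.alt,
                        _fmt(af), _fmt(maf), "-",
                        _fmt(rsq) if rsq is not None else "-",
                        "Genotyped" if genotyped else "Imputed",
                    ]
                )
                + "\n"
            )
            records.append(
                BatchInfoRecord(key=key, af=af, maf=maf, rsq=rsq, genotyped=genotyped, n_samples=n)
            )
    return InfoTable(records=records, column_dialect={"source": "vcf-info"})
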