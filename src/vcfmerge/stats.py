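"""Cross-batch summary statistics.

Imputation quality (R-squared between imputed dosage and true genotype) is
not safely averaged on its own scale: the sampling distribution of a
correlation coefficient is skewed, increasingly so near 1. The standard
remedy is Fisher's variance-stabilizing z-transformation: take
r = sqrt(R^2), map z = arctanh(r), average the z-values weighted by batch
sample size, and back-transform with tanh. This module implements that
combination plus the simpler weighted-mean / min / max aggregation of
allele frequencies and the all/some/none genotyped-status lattice.

Batches in which a variant is absent contribute nothing; batches in which
the variant is present but carries a placeholder Rsq contribute to allele
frequency and genotyped status but are left out of the z-combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .formats import VariantKey

__all__ = [
    "GenotypedStatus",
    "ExclusionReason",
    "CombinedInfoRecord",
    "combine_rsq",
    "combine_af",
    "combine_genotyped_status",
    "RSQ_CLAMP",
]

#: r is clamped to 1 - RSQ_CLAMP before arctanh so genotyped variants with
#: R^2 = 1 map to a large finite z instead of infinity.
RSQ_CLAMP = 1e-6


class GenotypedStatus(str, Enum):
    ALL = "all"
    SOME = "some"
    NONE = "none"


class ExclusionReason(str, Enum):
    TOO_MANY_MISSING = "too-many-missing"
    BELOW_THRESHOLD = "below-threshold"


@dataclass
class CombinedInfoRecord:
    """Cross-batch summary for one variant."""

    key: VariantKey
    rsq_combined: float | None
    rsq_min: float | None
    rsq_max: float | None
    af_weighted: float
    af_min: float
    af_max: float
    maf_weighted: float
    maf_min: float
    maf_max: float
    genotyped_status: GenotypedStatus
    n_missing_batches: int
    n_effective: int
    retained: bool = True
    exclusion_reason: ExclusionReason | None = None


def combine_rsq(per_batch: Sequence[tuple[float, float]]) -> float | None:
    """Combine per-batch imputation R-squared via Fisher z-transformation.

    Parameters
    ----------
    per_batch
        ``(rsq, weight)`` pairs for the batches that both contain the
        variant and report a quality value. Weights are batch sample
        counts (or n-3 under that convention); they must be positive.

    Returns
    -------
    The combined R-squared, ``tanh(sum(w*arctanh(sqrt(rsq)))/sum(w))**2``,
    or ``None`` for empty input (quality unavailable). Deterministic and
    independent of input order and of a common rescaling of the weights.
    """
    if not per_batch:
        return None
    rsq = np.asarray([p[0] for p in per_batch], dtype=np.float64)
    w = np.asarray([p[1] for p in per_batch], dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("combine_rsq: all weights must be positive")
    if np.any((rsq < 0) | (rsq > 1)):
        raise ValueError("combine_rsq: Rsq values must lie in [0,1]")
    r = np.minimum(np.sqrt(rsq), 1.0 - RSQ_CLAMP)
    z = np.arctanh(r)
    # canonical summation order (z, then weight) so the result is bitwise
    # identical under any permutation of the input batches
    order = np.lexsort((w, z))
    zbar = float(np.sum(z[order] * w[order]) / np.sum(w[order]))
    return float(np.tanh(zbar) ** 2)


def combine_af(
    per_batch: Sequence[tuple[float, float]],
) -> tuple[float, float, float] | None:
    """Weighted mean, min and max of a frequency across contributing batches.

    Serves both ALT frequency and MAF. Returns ``None`` for empty input.
    """
    if not per_batch:
        return None
    vals = np.asarray([p[0] for p in per_batch], dtype=np.float64)
    w = np.asarray([p[1] for p in per_batch], dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("combine_af: all weights must be positive")
    order = np.lexsort((w, vals))
    mean = float(np.sum(vals[order] * w[order]) / np.sum(w[order]))
    return mean, float(vals.min()), float(vals.max())


def combine_genotyped_status(flags: Sequence[bool]) -> GenotypedStatus:
    """all / some / none over the genotyped flags of contributing batches."""
    if len(flags) == 0:
        raise ValueError("combine_genotyped_status: empty flag sequence")
    if all(flags):
        return GenotypedStatus.ALL
    if any(flags):
        return GenotypedStatus.SOME
    return GenotypedStatus.NONE
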