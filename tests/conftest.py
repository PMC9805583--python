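import math

import pytest

from vcfmerge import CohortSpec, generate_cohort


def fisher_combine_oracle(pairs, clamp=1e-6):
    """Reference Fisher z-combination, coded independently of the package.

    Plain-Python loop over math functions: r = sqrt(R2) clamped below 1,
    z = arctanh(r) averaged with the given weights, back-transformed and
    squared.
    """
    num = 0.0
    den = 0.0
    for rsq, w in pairs:
        r = min(math.sqrt(rsq), 1.0 - clamp)
        z = math.atanh(r)
        num += w * z
        den += w
    return math.tanh(num / den) ** 2


@pytest.fixture
def small_cohort():
    return generate_cohort(CohortSpec(n_samples=6, n_variants=50, seed=11))
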