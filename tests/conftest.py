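import math
from fractions import Fraction

import pytest

from estdigex.est_model_io import ESTLibrary, TissueClass


def exact_binomial_pmf(n: int, N: int, f: Fraction) -> Fraction:
    """Independent oracle: C(N,n) f^n (1-f)^(N-n) in exact rational arithmetic."""
    return math.comb(N, n) * f**n * (1 - f) ** (N - n)


def exact_log_pmf(n: int, N: int, f: Fraction) -> float:
    """log of the exact pmf, evaluated without ever forming a small float."""
    p = exact_binomial_pmf(n, N, f)
    if p == 0:
        return float("-inf")
    return math.log(p.numerator) - math.log(p.denominator)


@pytest.fixture
def small_libraries() -> list[ESTLibrary]:
    """Two inflorescence libraries plus one per other pool except stem."""
    return [
        ESTLibrary("infl_1", TissueClass.INFLORESCENCE, 10000),
        ESTLibrary("infl_2", TissueClass.INFLORESCENCE, 20000),
        ESTLibrary("root_1", TissueClass.ROOT, 15000),
        ESTLibrary("leaf_1", TissueClass.LEAF, 12000),
        ESTLibrary("seed_1", TissueClass.SEED, 18000),
    ]
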