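"""Neutral-expectation Poisson framework for mutation counts.

A single clone propagated for ``t`` generations accumulates neutral
mutations at rate ``mu`` per bp per generation over a genome of ``L`` bp per
haploid set, so the expected count is ``lambda = mu * L * ploidy * t``.
Observed counts are tested against Poisson(lambda) with an exact upper tail,
and an observed total can be partitioned into sub-classes (coding,
non-synonymous) via a class probability ``p``.

Ploidy is an explicit factor (default 2): the diploid genome presents twice
the haploid target.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps

from .errors import ConfigError
from .genome import SACCHAROMYCES_NUCLEAR_BP

#: Per-bp per-generation mutation rate measured at the CAN1 reporter locus
#: (Lang & Murray), the most generous published estimate for budding yeast.
DEFAULT_MU = 6.44e-10


@dataclass(frozen=True)
class NeutralModel:
    """Parameters of the neutral mutation-count expectation."""

    mu: float = DEFAULT_MU
    L: int = SACCHAROMYCES_NUCLEAR_BP
    ploidy: int = 2
    t: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.L <= 0 or self.ploidy < 1 or self.t < 0:
            raise ConfigError(f"invalid neutral model {self}")

    @property
    def expectation(self) -> float:
        return self.mu * self.L * self.ploidy * self.t


@dataclass(frozen=True)
class CountTestResult:
    observed: int
    expected: float
    p_upper: float


def expected_neutral(model: NeutralModel) -> float:
    """lambda = mu * L * ploidy * t."""
    return model.expectation


def poisson_upper_tail(observed: int, lam: float) -> float:
    """Exact P(X >= observed) for X ~ Poisson(lam).

    Computed via the survival function (regularized incomplete gamma), which
    is stable for the small-lambda / moderate-count regime used here.
    """
    if observed < 0 or lam <= 0:
        raise ConfigError(f"need observed >= 0 and lambda > 0, got "
                          f"({observed}, {lam})")
    if observed == 0:
        return 1.0
    return float(sps.poisson.sf(observed - 1, lam))


def count_test(observed: int, model: NeutralModel) -> CountTestResult:
    lam = model.expectation
    return CountTestResult(observed, lam, poisson_upper_tail(observed, lam))


def partition_expectation(n: int, p: float,
                          observed: int | None = None) -> CountTestResult:
    """Expected sub-count ``n * p`` of an observed total, with a Poisson
    upper tail for an observed sub-count when one is supplied.

    E.g. of 28 observed mutations with coding probability 0.721, between 20
    and 21 are expected to be coding.
    """
    if n < 0 or not 0.0 <= p <= 1.0:
        raise ConfigError(f"need n >= 0 and p in [0,1], got ({n}, {p})")
    expected = n * p
    if observed is None:
        return CountTestResult(observed=-1, expected=expected, p_upper=float("nan"))
    if expected == 0:
        return CountTestResult(observed, 0.0, 1.0 if observed == 0 else 0.0)
    return CountTestResult(observed, expected, poisson_upper_tail(observed, expected))
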