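"""Closed-form win probabilities for the mixability comparison.

The asexual comparison pits one observation from each allele's fitness
distribution against the other: the more-mixable allele is correctly
identified when its single draw is larger.  The sexual comparison pits the
*means* of many draws — by the CLT the sample mean of M draws from a
distribution with mean E and standard deviation s is approximately
Normal(E, s / sqrt(M)), so both cases reduce to the probability that one
normal variable exceeds another:

    P(A > B) = Phi((E_A - E_B) / sqrt(s_A**2 + s_B**2)).

Calibrating the mixability ratio to d multiplies one allele's fitness values
by ~sqrt(d) and the other's by ~1/sqrt(d), scaling the base fitness
distribution Normal(E, sigma) accordingly.  In the two-allele diploid model
the relevant comparison is between the two homozygote classes (the shared
heterozygote cancels), whose calibrated ratio is 2d - 1 instead of d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TheoryQuery:
    """Inputs for the closed-form win probability.

    ``samples_per_allele`` is the CLT sample size M: 1 for the asexual
    single-observation comparison; for the sexual comparison the default used
    throughout is the expected number of carriers of each allele,
    ``N * ploidy / n``.  ``use_truncated_moments`` replaces (mean, sd) by the
    exact moments of the [0, 1]-truncated normal before scaling.
    """

    d: float = 1.0112
    mean: float = 0.7
    sd: float = 0.15
    samples_per_allele: int = 1000
    ploidy: int = 1
    use_truncated_moments: bool = False

    def __post_init__(self) -> None:
        if self.samples_per_allele < 1:
            raise ValueError("samples_per_allele must be at least 1")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.ploidy == 2 and 2 * self.d - 1 <= 0:
            raise ValueError("the diploid homozygote ratio 2d - 1 must be positive")
        if self.d <= 0:
            raise ValueError("d must be positive")


def default_samples_per_allele(N: int, ploidy: int, n: int) -> int:
    """Expected carrier count of each focal allele at uniform frequencies."""
    return max(1, round(N * ploidy / n))


def truncated_moments(
    mean: float, sd: float, lo: float = 0.0, hi: float = 1.0
) -> tuple[float, float]:
    """Exact mean and sd of a Normal(mean, sd) doubly truncated to [lo, hi]."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not lo < hi:
        raise ValueError("lower bound must be below upper bound")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    m, v = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(m), float(math.sqrt(v))


def prob_normal_greater(a: NormalSpec, b: NormalSpec) -> float:
    """P(A > B) for independent normals; defined as 0.5 when both are the
    same point mass."""
    spread = math.hypot(a.sd, b.sd)
    diff = a.mean - b.mean
    if spread == 0.0:
        return 0.5 if diff == 0.0 else float(diff > 0.0)
    return float(stats.norm.sf(-diff / spread))


def _allele_distributions(q: TheoryQuery) -> tuple[NormalSpec, NormalSpec]:
    """Fitness distributions of the two alleles' carriers after calibration."""
    base_mean, base_sd = q.mean, q.sd
    if q.use_truncated_moments:
        base_mean, base_sd = truncated_moments(q.mean, q.sd)
    ratio = q.d if q.ploidy == 1 else 2.0 * q.d - 1.0
    up = math.sqrt(ratio)
    return (
        NormalSpec(base_mean * up, base_sd * up),
        NormalSpec(base_mean / up, base_sd / up),
    )


def sex_theoretical_P(q: TheoryQuery) -> float:
    """CLT probability that the more-mixable allele's sample-mean fitness
    exceeds its rival's, with M = samples_per_allele draws each."""
    a, b = _allele_distributions(q)
    root = math.sqrt(q.samples_per_allele)
    return prob_normal_greater(
        NormalSpec(a.mean, a.sd / root), NormalSpec(b.mean, b.sd / root)
    )


def asex_theoretical_P(q: TheoryQuery) -> float:
    """Single-observation comparison: the sexual formula at M = 1.

    In the diploid model the heterozygote contribution cancels from both
    sides, leaving the independent homozygote classes with ratio 2d - 1.
    """
    return sex_theoretical_P(
        TheoryQuery(
            d=q.d,
            mean=q.mean,
            sd=q.sd,
            samples_per_allele=1,
            ploidy=q.ploidy,
            use_truncated_moments=q.use_truncated_moments,
        )
    )


def monte_carlo_P(
    q: TheoryQuery, draws: int, rng: np.random.Generator
) -> float:
    """Direct simulation of the defining probability (sample-mean comparison
    with normal draws); cross-checks the closed form."""
    a, b = _allele_distributions(q)
    m = q.samples_per_allele
    A = rng.normal(a.mean, a.sd, size=(draws, m)).mean(axis=1)
    B = rng.normal(b.mean, b.sd, size=(draws, m)).mean(axis=1)
    return float((A > B).mean() + 0.5 * (A == B).mean())


def theory_table(
    d_values,
    N: int = 2000,
    ploidy: int = 1,
    mean: float = 0.7,
    sd: float = 0.15,
    n: int = 2,
    use_truncated_moments: bool = False,
) -> list[dict]:
    """Rows of (d, sexual P, asexual P) for a list of mixability ratios."""
    rows = []
    M = default_samples_per_allele(N, ploidy, n)
    for d in d_values:
        q = TheoryQuery(
            d=d,
            mean=mean,
            sd=sd,
            samples_per_allele=M,
            ploidy=ploidy,
            use_truncated_moments=use_truncated_moments,
        )
        rows.append(
            {
                "d": d,
                "ploidy": ploidy,
                "samples_per_allele": M,
                "sex_P": sex_theoretical_P(q),
                "asex_P": asex_theoretical_P(q),
            }
        )
    return rows
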