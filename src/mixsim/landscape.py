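"""Epistatic fitness landscapes with calibrated allele mixabilities.

A landscape assigns every multilocus genotype a fitness in [0, 1], interpreted
as a survival probability.  Haploid landscapes live on the full tensor of
``n**L`` genotypes; diploid landscapes on ``(n*(n+1)//2)**L`` genotypes, one
entry per tuple of unordered within-locus allele pairs (no position effects).

The mixability of an allele is the unweighted mean fitness of every genotype
carrying it.  The calibration routines rescale the fitnesses of two focal
alleles so that their mixability ratio hits an exact target ``d``: the
carriers of the favoured allele are multiplied by ``sqrt(d * mu_j / mu_i)``
and the carriers of its rival by the reciprocal factor, which leaves the
product of the two mixabilities invariant and sets their ratio to ``d``
exactly.  In the diploid two-allele case the shared heterozygote forces a
``2d - 1`` correction on the homozygote classes instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 10**6


class LandscapeError(ValueError):
    """Raised for degenerate or infeasible landscape configurations."""


@dataclass(frozen=True)
class FocalPair:
    """A pair of alleles at one locus whose mixability ratio is calibrated.

    ``allele_i`` is the allele pushed up to be more mixable by the factor
    implied by ``target_ratio`` (d); ``allele_j`` is pushed down.
    """

    locus: int = 0
    allele_i: int = 0
    allele_j: int = 1
    target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.allele_i == self.allele_j:
            raise ValueError("focal alleles must differ")
        if self.target_ratio <= 0:
            raise ValueError("target mixability ratio must be positive")


@dataclass(frozen=True)
class FitnessSpec:
    """Distribution of raw (pre-calibration) genotype fitness values.

    Continuous mode draws from Normal(mean, sd) with out-of-bounds values
    rejected and redrawn (never clipped), so the realised distribution is the
    doubly truncated normal on [lo, hi].
    """

    mean: float = 0.7
    sd: float = 0.15
    lo: float = 0.0
    hi: float = 1.0
    mode: str = "continuous"  # "continuous" | "binary"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lo < self.hi:
            raise ValueError("lower bound must be below upper bound")
        if self.mode not in ("continuous", "binary"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")


def sample_truncated_fitness(
    spec: FitnessSpec, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` fitness values by rejection from a truncated normal.

    Values outside ``[spec.lo, spec.hi]`` are replaced by fresh draws from the
    same Normal(mean, sd) until all fall inside the interval.
    """
    if spec.mode != "continuous":
        raise ValueError("sampling requires a continuous fitness spec")
    if count < 0:
        raise ValueError("count must be non-negative")
    out = rng.normal(spec.mean, spec.sd, size=count)
    bad = (out < spec.lo) | (out > spec.hi)
    redraws = 0
    while bad.any():
        nbad = int(bad.sum())
        redraws += nbad
        if redraws > _MAX_REDRAWS:
            raise LandscapeError(
                "rejection sampling failed to converge; the acceptance "
                "region has negligible probability mass"
            )
        out[bad] = rng.normal(spec.mean, spec.sd, size=nbad)
        bad = (out < spec.lo) | (out > spec.hi)
    return out


def _check_axes(num_loci: int, alleles_per_locus: int) -> None:
    if num_loci < 1:
        raise ValueError("need at least one locus")
    if alleles_per_locus < 2:
        raise ValueError("need at least two alleles per locus")


@dataclass
class HaploidLandscape:
    """Fitness tensor over all ``n**L`` haploid genotypes.

    ``fitness[i1, ..., iL]`` is the survival probability of the genotype with
    allele ``i_l`` at locus ``l``.  Values may transiently exceed 1 after
    calibration; survival uses ``min(w, 1)`` (see :meth:`survival_prob`).
    """

    num_loci: int
    alleles_per_locus: int
    fitness: np.ndarray = field(repr=False)

    def __init__(self, num_loci: int, alleles_per_locus: int, fitness: np.ndarray):
        _check_axes(num_loci, alleles_per_locus)
        fitness = np.asarray(fitness, dtype=float)
        expected = (alleles_per_locus,) * num_loci
        if fitness.shape != expected:
            raise ValueError(
                f"fitness tensor shape {fitness.shape} != expected {expected}"
            )
        self.num_loci = num_loci
        self.alleles_per_locus = alleles_per_locus
        self.fitness = fitness

    @property
    def num_genotypes(self) -> int:
        return self.alleles_per_locus**self.num_loci

    @classmethod
    def random(
        cls,
        num_loci: int,
        alleles_per_locus: int,
        spec: FitnessSpec,
        rng: np.random.Generator,
    ) -> "HaploidLandscape":
        """Draw a fresh landscape with iid truncated-normal fitnesses."""
        shape = (alleles_per_locus,) * num_loci
        values = sample_truncated_fitness(spec, int(np.prod(shape)), rng)
        return cls(num_loci, alleles_per_locus, values.reshape(shape))

    def survival_prob(self, flat_index: np.ndarray) -> np.ndarray:
        """Survival probabilities for genotypes given as flat tensor indices."""
        return np.minimum(self.fitness.reshape(-1)[flat_index], 1.0)

    def flat_index(self, genotypes: np.ndarray) -> np.ndarray:
        """Map an array of genotypes (..., L) of allele indices to flat indices."""
        g = np.asarray(genotypes)
        return np.ravel_multi_index(
            tuple(g[..., l] for l in range(self.num_loci)),
            self.fitness.shape,
        )

    def copy(self) -> "HaploidLandscape":
        return HaploidLandscape(
            self.num_loci, self.alleles_per_locus, self.fitness.copy()
        )


def mixability_haploid(land: HaploidLandscape, locus: int, allele: int) -> float:
    """Unweighted mean fitness of the ``n**(L-1)`` genotypes carrying ``allele``."""
    if not 0 <= locus < land.num_loci:
        raise IndexError(f"locus {locus} out of range")
    if not 0 <= allele < land.alleles_per_locus:
        raise IndexError(f"allele {allele} out of range")
    return float(np.take(land.fitness, allele, axis=locus).mean())


def _warn_capped(values: np.ndarray) -> None:
    ncap = int((values > 1.0).sum())
    if ncap:
        # cap rates up to ~2% are expected at the default E, sigma and the
        # panel-grid d values; only an unusual landscape warrants a visible
        # warning
        level = logging.WARNING if ncap > 0.05 * values.size else logging.DEBUG
        logger.log(
            level,
            "calibration pushed %d of %d fitness value(s) above 1; survival "
            "uses min(w, 1)",
            ncap,
            values.size,
        )


def adjust_haploid_pair(
    land: HaploidLandscape, focal: FocalPair, inplace: bool = False
) -> HaploidLandscape:
    """Rescale the carriers of the two focal alleles so their mixability
    ratio equals ``focal.target_ratio`` exactly.

    Carriers of ``allele_i`` are multiplied by ``sqrt(d * mu_j / mu_i)`` and
    carriers of ``allele_j`` by the reciprocal; all other genotypes are left
    bitwise untouched.
    """
    out = land if inplace else land.copy()
    mu_i = mixability_haploid(out, focal.locus, focal.allele_i)
    mu_j = mixability_haploid(out, focal.locus, focal.allele_j)
    if mu_j <= 0 or mu_i <= 0:
        raise LandscapeError("focal allele has zero mixability; cannot calibrate")
    factor = np.sqrt(focal.target_ratio * mu_j / mu_i)
    sl_i = (slice(None),) * focal.locus + (focal.allele_i,)
    sl_j = (slice(None),) * focal.locus + (focal.allele_j,)
    out.fitness[sl_i] *= factor
    out.fitness[sl_j] /= factor
    _warn_capped(out.fitness)
    return out


def adjust_all_loci(
    land: HaploidLandscape, focal_pairs: list[FocalPair]
) -> HaploidLandscape:
    """Apply the pairwise calibration sequentially, one locus after another.

    Each step uses the already-transformed tensor, so only the last locus's
    ratio is exact; earlier loci end up approximately at their targets.
    """
    loci = sorted(p.locus for p in focal_pairs)
    if loci != sorted(set(loci)):
        raise ValueError("at most one focal pair per locus")
    out = land.copy()
    for pair in sorted(focal_pairs, key=lambda p: p.locus):
        adjust_haploid_pair(out, pair, inplace=True)
    return out


# ---------------------------------------------------------------------------
# diploid


def pair_index_table(n: int) -> np.ndarray:
    """(n, n) table mapping an ordered allele pair to its canonical index.

    Pairs are enumerated with min(i, j) first: for n=2 the order is
    (0,0) -> 0, (0,1) -> 1, (1,1) -> 2.
    """
    table = np.empty((n, n), dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i, n):
            table[i, j] = table[j, i] = k
            k += 1
    return table


def pair_list(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i, n)]


@dataclass
class DiploidLandscape:
    """Fitness tensor over unordered within-locus allele pairs.

    The per-locus axis indexes the ``n*(n+1)//2`` canonical pairs, so the
    (i, j) and (j, i) orderings at any locus resolve to the same entry — the
    model has no position effects.
    """

    num_loci: int
    alleles_per_locus: int
    fitness: np.ndarray = field(repr=False)

    def __init__(self, num_loci: int, alleles_per_locus: int, fitness: np.ndarray):
        _check_axes(num_loci, alleles_per_locus)
        m = alleles_per_locus * (alleles_per_locus + 1) // 2
        fitness = np.asarray(fitness, dtype=float)
        expected = (m,) * num_loci
        if fitness.shape != expected:
            raise ValueError(
                f"fitness tensor shape {fitness.shape} != expected {expected}"
            )
        self.num_loci = num_loci
        self.alleles_per_locus = alleles_per_locus
        self.fitness = fitness
        self._pair_table = pair_index_table(alleles_per_locus)

    @property
    def pairs_per_locus(self) -> int:
        return self.alleles_per_locus * (self.alleles_per_locus + 1) // 2

    @property
    def num_genotypes(self) -> int:
        return self.pairs_per_locus**self.num_loci

    @classmethod
    def random(
        cls,
        num_loci: int,
        alleles_per_locus: int,
        spec: FitnessSpec,
        rng: np.random.Generator,
    ) -> "DiploidLandscape":
        m = alleles_per_locus * (alleles_per_locus + 1) // 2
        shape = (m,) * num_loci
        values = sample_truncated_fitness(spec, int(np.prod(shape)), rng)
        return cls(num_loci, alleles_per_locus, values.reshape(shape))

    def pair_indices(self, hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
        """Canonical per-locus pair indices for two haplotype arrays (..., L)."""
        return self._pair_table[np.asarray(hap_a), np.asarray(hap_b)]

    def flat_index(self, hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
        pairs = self.pair_indices(hap_a, hap_b)
        return np.ravel_multi_index(
            tuple(pairs[..., l] for l in range(self.num_loci)),
            self.fitness.shape,
        )

    def survival_prob(self, flat_index: np.ndarray) -> np.ndarray:
        return np.minimum(self.fitness.reshape(-1)[flat_index], 1.0)

    def lookup(self, genotype_pairs) -> float:
        """Fitness of one genotype given as a sequence of (i, j) pairs."""
        idx = tuple(self._pair_table[i, j] for (i, j) in genotype_pairs)
        return float(self.fitness[idx])

    def copy(self) -> "DiploidLandscape":
        return DiploidLandscape(
            self.num_loci, self.alleles_per_locus, self.fitness.copy()
        )


def _carrier_pair_ids(n: int, allele: int) -> list[int]:
    table = pair_index_table(n)
    return sorted({int(table[allele, k]) for k in range(n)})


def mixability_diploid(land: DiploidLandscape, locus: int, allele: int) -> float:
    """Mean fitness over genotypes whose focal-locus pair contains ``allele``.

    Normalised by ``n * (n(n+1)/2)**(L-1)``: the sum runs over the n pairs
    (allele, k), each combined with every configuration of the other loci.
    """
    if not 0 <= locus < land.num_loci:
        raise IndexError(f"locus {locus} out of range")
    n = land.alleles_per_locus
    if not 0 <= allele < n:
        raise IndexError(f"allele {allele} out of range")
    carriers = _carrier_pair_ids(n, allele)
    total = sum(
        float(np.take(land.fitness, pid, axis=locus).sum()) for pid in carriers
    )
    denom = n * land.pairs_per_locus ** (land.num_loci - 1)
    return total / denom


def adjust_diploid_pair(
    land: DiploidLandscape,
    focal: FocalPair,
    correction: str = "exact_two_allele",
    inplace: bool = False,
) -> DiploidLandscape:
    """Calibrate a diploid landscape so the focal carrier-mixability ratio ~ d.

    The heterozygote class shared by the two focal alleles is left untouched
    in both modes.  With ``correction="exact_two_allele"`` (the n=2 case) the
    homozygote-like carrier classes are rescaled so that the ratio of the
    i-carrier (minus heterozygote) fitness sum to the j-carrier (minus
    heterozygote) sum equals ``2d - 1`` exactly, which makes the full carrier
    ratio equal d up to the sampling fluctuation of the heterozygote sum.
    With ``correction="large_n"`` the plain ratio d is used instead, accurate
    when the shared class is a vanishing fraction of the carriers.
    """
    if correction not in ("exact_two_allele", "large_n"):
        raise ValueError(f"unknown correction {correction!r}")
    d = focal.target_ratio
    if correction == "exact_two_allele":
        ratio = 2.0 * d - 1.0
        if ratio <= 0:
            raise LandscapeError("2d - 1 must be positive for the exact correction")
    else:
        ratio = d
    out = land if inplace else land.copy()
    n = out.alleles_per_locus
    table = pair_index_table(n)
    het = int(table[focal.allele_i, focal.allele_j])
    ids_i = [p for p in _carrier_pair_ids(n, focal.allele_i) if p != het]
    ids_j = [p for p in _carrier_pair_ids(n, focal.allele_j) if p != het]
    sum_i = sum(float(np.take(out.fitness, p, axis=focal.locus).sum()) for p in ids_i)
    sum_j = sum(float(np.take(out.fitness, p, axis=focal.locus).sum()) for p in ids_j)
    if sum_i <= 0 or sum_j <= 0:
        raise LandscapeError("degenerate landscape: zero carrier fitness sum")
    factor = np.sqrt(ratio * sum_j / sum_i)
    for p in ids_i:
        out.fitness[(slice(None),) * focal.locus + (p,)] *= factor
    for p in ids_j:
        out.fitness[(slice(None),) * focal.locus + (p,)] /= factor
    _warn_capped(out.fitness)
    return out


# ---------------------------------------------------------------------------
# binary (0/1) landscapes


def _binary_fill(
    carrier_flat: np.ndarray,
    parent_flat: np.ndarray,
    frac_one: float,
    values: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Among `carrier_flat` cells, set exactly round(frac_one * count) to 1
    (parents forced to 1) and the rest to 0."""
    total = carrier_flat.size
    ones_needed = int(round(frac_one * total))
    parents = np.intersect1d(parent_flat, carrier_flat)
    if parents.size > ones_needed:
        raise LandscapeError(
            f"infeasible binary fill: {parents.size} parent genotypes exceed the "
            f"{ones_needed} fitness-1 slots implied by fraction {frac_one}"
        )
    free = np.setdiff1d(carrier_flat, parents)
    extra = ones_needed - parents.size
    chosen = rng.choice(free, size=extra, replace=False) if extra else free[:0]
    values[carrier_flat] = 0.0
    values[parents] = 1.0
    values[chosen] = 1.0


def build_binary_haploid(
    num_loci: int,
    alleles_per_locus: int,
    parent_genotypes: np.ndarray,
    frac_one_i: float,
    frac_one_j: float,
    rng: np.random.Generator,
    focal: FocalPair | None = None,
) -> HaploidLandscape:
    """Build a 0/1 haploid landscape with prescribed fitness-1 fractions.

    Every parent genotype gets fitness 1 (survivors must be viable); among the
    remaining carriers of each focal allele zeros are placed uniformly at
    random so the fraction of fitness-1 genotypes among carriers of allele i
    (resp. j) equals ``frac_one_i`` (resp. ``frac_one_j``) to the nearest
    achievable count.  The realised mixability ratio is then
    ``frac_one_i / frac_one_j``.
    """
    focal = focal or FocalPair(target_ratio=max(frac_one_i / frac_one_j, 1e-9))
    n, L = alleles_per_locus, num_loci
    land = HaploidLandscape(L, n, np.ones((n,) * L))
    flat = land.fitness.reshape(-1)
    parents = np.asarray(parent_genotypes).reshape(-1, L)
    parent_flat = np.unique(land.flat_index(parents))
    all_geno = np.arange(n**L)
    locus_allele = (all_geno // (n ** (L - 1 - focal.locus))) % n
    for allele, frac in ((focal.allele_i, frac_one_i), (focal.allele_j, frac_one_j)):
        carriers = all_geno[locus_allele == allele]
        _binary_fill(carriers, parent_flat, frac, flat, rng)
    # non-carrier genotypes (n > 2): ones at the majority rate, parents forced
    others = all_geno[
        (locus_allele != focal.allele_i) & (locus_allele != focal.allele_j)
    ]
    if others.size:
        _binary_fill(others, parent_flat, frac_one_i, flat, rng)
    return land


def build_binary_diploid(
    num_loci: int,
    alleles_per_locus: int,
    parent_pair_genotypes: np.ndarray,
    frac_one_i: float,
    frac_one_j: float,
    rng: np.random.Generator,
    focal: FocalPair | None = None,
) -> DiploidLandscape:
    """Binary diploid landscape; the shared heterozygote class counts toward
    both alleles' fitness-1 fractions.

    ``parent_pair_genotypes`` is an array (k, L) of flat-able canonical
    pair-index rows (use ``DiploidLandscape.pair_indices`` on haplotypes).
    Heterozygote carriers are filled at the mean of the two target rates, then
    each allele's exclusive carrier class is topped up to hit its own target
    exactly, which fixes the realised ratio at ``frac_one_i / frac_one_j`` to
    the nearest achievable counts.
    """
    focal = focal or FocalPair(target_ratio=max(frac_one_i / frac_one_j, 1e-9))
    n, L = alleles_per_locus, num_loci
    m = n * (n + 1) // 2
    land = DiploidLandscape(L, n, np.ones((m,) * L))
    flat = land.fitness.reshape(-1)
    table = pair_index_table(n)
    het = int(table[focal.allele_i, focal.allele_j])
    parents = np.asarray(parent_pair_genotypes).reshape(-1, L)
    parent_flat = np.unique(
        np.ravel_multi_index(tuple(parents[:, l] for l in range(L)), (m,) * L)
    )
    all_geno = np.arange(m**L)
    locus_pair = (all_geno // (m ** (L - 1 - focal.locus))) % m
    ids_i = _carrier_pair_ids(n, focal.allele_i)
    ids_j = _carrier_pair_ids(n, focal.allele_j)
    het_set = all_geno[locus_pair == het]
    excl_i = all_geno[np.isin(locus_pair, [p for p in ids_i if p != het])]
    excl_j = all_geno[np.isin(locus_pair, [p for p in ids_j if p != het])]
    # shared heterozygote class at the mean rate
    _binary_fill(het_set, parent_flat, 0.5 * (frac_one_i + frac_one_j), flat, rng)
    for excl, carriers_total, frac in (
        (excl_i, het_set.size + excl_i.size, frac_one_i),
        (excl_j, het_set.size + excl_j.size, frac_one_j),
    ):
        target_ones = int(round(frac * carriers_total))
        het_ones = int(flat[het_set].sum())
        excl_frac = (target_ones - het_ones) / excl.size
        if not 0.0 <= excl_frac <= 1.0:
            raise LandscapeError(
                "infeasible binary diploid fill: heterozygote ones exceed the "
                "carrier target"
            )
        _binary_fill(excl, parent_flat, excl_frac, flat, rng)
    others = all_geno[~np.isin(locus_pair, sorted(set(ids_i) | set(ids_j)))]
    if others.size:
        _binary_fill(others, parent_flat, frac_one_i, flat, rng)
    return land


# ---------------------------------------------------------------------------
# tabular I/O


def landscape_to_frame(land: HaploidLandscape | DiploidLandscape) -> pd.DataFrame:
    """One row per genotype: allele columns (diploid: 2L, canonical order
    within each locus) plus a fitness column."""
    L = land.num_loci
    if isinstance(land, HaploidLandscape):
        rows = list(itertools.product(range(land.alleles_per_locus), repeat=L))
        df = pd.DataFrame(rows, columns=[f"locus{l}" for l in range(L)])
        df["fitness"] = land.fitness.reshape(-1)
        return df
    pairs = pair_list(land.alleles_per_locus)
    rows = []
    for combo in itertools.product(range(len(pairs)), repeat=L):
        row: list[int] = []
        for pid in combo:
            row.extend(pairs[pid])
        rows.append(row)
    cols = [f"locus{l}_{ab}" for l in range(L) for ab in ("a", "b")]
    df = pd.DataFrame(rows, columns=cols)
    df["fitness"] = land.fitness.reshape(-1)
    return df


def write_landscape(land: HaploidLandscape | DiploidLandscape, path) -> None:
    ploidy = 1 if isinstance(land, HaploidLandscape) else 2
    with open(path, "w") as fh:
        fh.write(
            f"# L={land.num_loci} n={land.alleles_per_locus} ploidy={ploidy}\n"
        )
        landscape_to_frame(land).to_csv(fh, sep="\t", index=False)


def read_landscape(path) -> HaploidLandscape | DiploidLandscape:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    L, n, ploidy = int(meta["L"]), int(meta["n"]), int(meta["ploidy"])
    if ploidy == 1:
        land = HaploidLandscape(L, n, np.empty((n,) * L))
        idx = np.ravel_multi_index(
            tuple(df[f"locus{l}"].to_numpy() for l in range(L)), (n,) * L
        )
    else:
        m = n * (n + 1) // 2
        land = DiploidLandscape(L, n, np.empty((m,) * L))
        table = pair_index_table(n)
        pids = [
            table[df[f"locus{l}_a"].to_numpy(), df[f"locus{l}_b"].to_numpy()]
            for l in range(L)
        ]
        idx = np.ravel_multi_index(tuple(pids), (m,) * L)
    land.fitness.reshape(-1)[idx] = df["fitness"].to_numpy()
    return land
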