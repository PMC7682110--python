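"""Recombination and mating schedules.

Recombination follows the Poisson model: the offspring copies locus 1 from a
uniformly chosen parent (or parental haplotype), and between each pair of
neighboring loci the source switches with probability ``r`` independently of
the other intervals.  ``r = 0.5`` is free recombination, ``r = 0`` transmits
an intact sequence.  Every recombination call also returns the complementary
product — the locus-wise opposite source choice — so that the two products
together carry each parental allele exactly once; the drift-free schedules
rely on this conservation.

Mating schedules come in three schemes (selfing-capable hermaphrodites, two
mating types with mating only across types, and clone-restricted mating for
the perfect-LD starts) and two drift modes.  With drift, parents are drawn
uniformly with replacement, so fertility and transmission are both random.
Without drift, each haploid parent appears in exactly one mating that yields
the two complementary offspring (each diploid parent in exactly two matings,
receiving the two complementary gametes), which removes all random variation
in fertility and transmission — at the cost of a fixed offspring count
instead of a fixed survivor count.
"""

from __future__ import annotations

import numpy as np

from .popgen import ConfigurationError, Population

HERMAPHRODITE = "hermaphrodite_selfing"
TWO_TYPES = "two_types"
CLONES_ONLY = "clones_only"
SCHEMES = (HERMAPHRODITE, TWO_TYPES, CLONES_ONLY)

WITH_DRIFT = "with_drift"
NO_DRIFT = "no_drift"


def _check_r(r: float) -> None:
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination rate {r} outside [0, 0.5]")


def source_walk(
    batch: int, num_loci: int, r: float, rng: np.random.Generator
) -> np.ndarray:
    """(batch, L) array of 0/1 parent sources under the Poisson model."""
    _check_r(r)
    start = rng.integers(0, 2, size=(batch, 1))
    if num_loci == 1:
        return start
    switches = (rng.random((batch, num_loci - 1)) < r).astype(np.int64)
    return (start + np.concatenate(
        [np.zeros((batch, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
    )) % 2


def recombine_batch(
    p1: np.ndarray, p2: np.ndarray, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Recombine row-aligned parent arrays (B, L); returns (offspring,
    complement), complementary in every row."""
    src = source_walk(p1.shape[0], p1.shape[1], r, rng)
    offspring = np.where(src == 0, p1, p2)
    complement = np.where(src == 0, p2, p1)
    return offspring, complement


def recombine_haploid(
    p1: np.ndarray, p2: np.ndarray, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pair convenience wrapper around :func:`recombine_batch`."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("parents must share the same number of loci")
    off, comp = recombine_batch(p1[None, :], p2[None, :], r, rng)
    return off[0], comp[0]


def make_gametes_batch(
    parents: np.ndarray, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Meiosis for a (B, 2, L) parent array: the same switch-walk applied to
    each parent's two haplotypes; returns (gamete, complement_gamete)."""
    return recombine_batch(parents[:, 0, :], parents[:, 1, :], r, rng)


def make_gamete(
    parent: np.ndarray, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    parent = np.asarray(parent)
    g, c = make_gametes_batch(parent[None, ...], r, rng)
    return g[0], c[0]


# ---------------------------------------------------------------------------
# parent sampling (with drift)


def _clone_groups(pop: Population) -> list[np.ndarray]:
    haplos = pop.genotypes.reshape(pop.size, -1)
    _, inverse = np.unique(haplos, axis=0, return_inverse=True)
    groups = [np.flatnonzero(inverse == k) for k in range(inverse.max() + 1)]
    if len(groups) != 2:
        raise ConfigurationError(
            f"clone-restricted mating expects exactly two clones, found {len(groups)}"
        )
    return groups


def draw_parent_pairs(
    pop: Population, scheme: str, count: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """``count`` independent uniform parent-index pairs under ``scheme``.

    Selfing hermaphrodites draw both parents with replacement (self-pairing
    has probability 1/N); two mating types draw one parent per type; clone
    restriction draws one parent from each of the two clones.
    """
    if scheme == HERMAPHRODITE:
        return (
            rng.integers(0, pop.size, size=count),
            rng.integers(0, pop.size, size=count),
        )
    if scheme == TWO_TYPES:
        if pop.mating_type is None:
            raise ConfigurationError("two-type mating requires mating-type labels")
        type1 = np.flatnonzero(pop.mating_type == 1)
        type2 = np.flatnonzero(pop.mating_type == 2)
        return (
            type1[rng.integers(0, type1.size, size=count)],
            type2[rng.integers(0, type2.size, size=count)],
        )
    if scheme == CLONES_ONLY:
        g1, g2 = _clone_groups(pop)
        return (
            g1[rng.integers(0, g1.size, size=count)],
            g2[rng.integers(0, g2.size, size=count)],
        )
    raise ConfigurationError(f"unknown mating scheme {scheme!r}")


def schedule_matings(
    pop: Population,
    scheme: str,
    drift: str,
    rng: np.random.Generator,
    batch: int = 1024,
):
    """Yield parent-index pairs under the given scheme and drift mode.

    With drift this is an unbounded stream of independent uniform pairs;
    without drift it is the finite complementary schedule — N/2 disjoint
    pairs for haploids, or the circular two-matings-per-parent schedule for
    diploids (yielding ``(parent_a, parent_b)`` per mating).
    """
    if drift == WITH_DRIFT:
        while True:
            i1, i2 = draw_parent_pairs(pop, scheme, batch, rng)
            yield from zip(i1, i2)
    elif drift == NO_DRIFT:
        if pop.ploidy == 1:
            i1, i2 = perfect_matching(pop, scheme, rng)
        else:
            i1, i2, _, _ = circular_schedule(pop, scheme, rng)
        yield from zip(i1, i2)
    else:
        raise ConfigurationError(f"unknown drift mode {drift!r}")


# ---------------------------------------------------------------------------
# drift-free schedules


def perfect_matching(
    pop: Population, scheme: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A uniform random perfect matching of the parents: N/2 disjoint pairs.

    Under two mating types each pair crosses the types; under clone
    restriction each pair crosses the clones (requires balanced halves).
    """
    if pop.size % 2 != 0:
        raise ConfigurationError("drift-free matching requires an even population")
    if scheme == HERMAPHRODITE:
        order = rng.permutation(pop.size)
        half = pop.size // 2
        return order[:half], order[half:]
    if scheme == TWO_TYPES:
        if pop.mating_type is None:
            raise ConfigurationError("two-type mating requires mating-type labels")
        type1 = np.flatnonzero(pop.mating_type == 1)
        type2 = np.flatnonzero(pop.mating_type == 2)
    else:
        type1, type2 = _clone_groups(pop)
    if type1.size != type2.size:
        raise ConfigurationError("drift-free cross mating requires balanced halves")
    return rng.permutation(type1), rng.permutation(type2)


def circular_schedule(
    pop: Population, scheme: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Drift-free diploid schedule: parents in random circular order, each
    mating with both neighbors and feeding one of its two complementary
    gametes to each mating.

    Returns ``(parent_a, parent_b, slot_a, slot_b)`` arrays of length N:
    mating k unites gamete ``slot_a[k]`` of ``parent_a[k]`` with gamete
    ``slot_b[k]`` of ``parent_b[k]``.  Under two mating types the circle
    alternates types so every mating crosses them.
    """
    N = pop.size
    if scheme == TWO_TYPES:
        if pop.mating_type is None:
            raise ConfigurationError("two-type mating requires mating-type labels")
        type1 = rng.permutation(np.flatnonzero(pop.mating_type == 1))
        type2 = rng.permutation(np.flatnonzero(pop.mating_type == 2))
        if type1.size != type2.size:
            raise ConfigurationError("two-type circle requires balanced types")
        order = np.empty(N, dtype=np.int64)
        order[0::2] = type1
        order[1::2] = type2
    else:
        order = rng.permutation(N)
    parent_a = order
    parent_b = np.roll(order, -1)
    slot_a = np.ones(N, dtype=np.int64)   # second complementary gamete forward
    slot_b = np.zeros(N, dtype=np.int64)  # first gamete backward
    return parent_a, parent_b, slot_a, slot_b
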