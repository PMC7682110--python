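"""Population containers and initialization schemes.

Haploid individuals are rows of an (N, L) integer array of allele indices;
diploid individuals carry two such haplotypes in an (N, 2, L) array.  Which
haplotype carries which allele at a locus never matters (no position
effects).  Initialization either deals alleles from an exactly balanced
per-locus store (uniform start, every allele at frequency 1/n exactly) or
stamps out copies of a few fixed clones (perfect linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    pass


@dataclass
class Population:
    """N individuals with optional two-mating-type labels.

    ``genotypes`` has shape (N, L) for haploids and (N, 2, L) for diploids.
    ``mating_type`` (values 1/2) is present only when the two-mating-types
    scheme is active.
    """

    genotypes: np.ndarray
    ploidy: int
    alleles_per_locus: int
    mating_type: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ConfigurationError("ploidy must be 1 or 2")
        expected_ndim = 2 if self.ploidy == 1 else 3
        if self.genotypes.ndim != expected_ndim:
            raise ConfigurationError(
                f"genotype array must be {expected_ndim}-dimensional for "
                f"ploidy {self.ploidy}"
            )
        if self.ploidy == 2 and self.genotypes.shape[1] != 2:
            raise ConfigurationError("diploid genotypes need two haplotypes")
        if self.mating_type is not None and len(self.mating_type) != self.size:
            raise ConfigurationError("one mating-type label per individual")

    @property
    def size(self) -> int:
        return self.genotypes.shape[0]

    @property
    def num_loci(self) -> int:
        return self.genotypes.shape[-1]

    def haplotypes(self) -> np.ndarray:
        """All allele-carrying sequences as a 2-D array (N*ploidy, L)."""
        if self.ploidy == 1:
            return self.genotypes
        return self.genotypes.reshape(-1, self.num_loci)


def init_uniform(
    N: int,
    num_loci: int,
    alleles_per_locus: int,
    ploidy: int,
    rng: np.random.Generator,
) -> Population:
    """Deal alleles from a balanced store: each allele appears exactly
    ``N * ploidy / n`` times at every locus, in uniform random order,
    independently across loci."""
    copies = N * ploidy
    if copies % alleles_per_locus != 0:
        raise ConfigurationError(
            f"allele store of {copies} copies cannot be split evenly among "
            f"{alleles_per_locus} alleles"
        )
    store = np.repeat(np.arange(alleles_per_locus, dtype=np.int64),
                      copies // alleles_per_locus)
    columns = [rng.permutation(store) for _ in range(num_loci)]
    haplos = np.column_stack(columns)
    if ploidy == 1:
        genos = haplos
    else:
        genos = haplos.reshape(N, 2, num_loci)
    return Population(genos, ploidy, alleles_per_locus)


def init_clonal(
    clones: np.ndarray, N: int, ploidy: int, alleles_per_locus: int
) -> Population:
    """N/len(clones) exact copies of each clone genotype.

    For haploids ``clones`` is (k, L); for diploids (k, 2, L).  The classic
    two-clone start uses the all-0 and all-1 genotypes (homozygous for
    diploids), giving every allele frequency exactly 1/2.
    """
    clones = np.asarray(clones)
    k = clones.shape[0]
    if N % k != 0:
        raise ConfigurationError(f"population size {N} not divisible by {k} clones")
    reps = N // k
    genos = np.repeat(clones, reps, axis=0)
    return Population(genos, ploidy, alleles_per_locus)


def two_clone_start(
    N: int, num_loci: int, ploidy: int, alleles_per_locus: int = 2
) -> Population:
    """The canonical perfect-LD start: clones (0,...,0) and (1,...,1)
    (homozygous in the diploid case)."""
    if ploidy == 1:
        clones = np.stack(
            [np.zeros(num_loci, dtype=np.int64), np.ones(num_loci, dtype=np.int64)]
        )
    else:
        clones = np.stack(
            [
                np.zeros((2, num_loci), dtype=np.int64),
                np.ones((2, num_loci), dtype=np.int64),
            ]
        )
    return init_clonal(clones, N, ploidy, alleles_per_locus)


def allele_frequency(pop: Population, locus: int, allele: int) -> float:
    """Fraction of allele copies at ``locus`` equal to ``allele``."""
    if pop.size == 0:
        raise ConfigurationError("empty population")
    if not 0 <= locus < pop.num_loci:
        raise IndexError(f"locus {locus} out of range")
    column = pop.haplotypes()[:, locus]
    return float((column == allele).mean())


def assign_mating_types(pop: Population, rng: np.random.Generator) -> Population:
    """Label exactly half the individuals type 1 and half type 2, uniformly."""
    if pop.size % 2 != 0:
        raise ConfigurationError("two mating types require an even population")
    labels = np.repeat(np.array([1, 2], dtype=np.int64), pop.size // 2)
    pop.mating_type = rng.permutation(labels)
    return pop


def population_to_frame(pop: Population) -> pd.DataFrame:
    L = pop.num_loci
    if pop.ploidy == 1:
        df = pd.DataFrame(pop.genotypes, columns=[f"locus{l}" for l in range(L)])
    else:
        flat = pop.genotypes.transpose(0, 2, 1).reshape(pop.size, 2 * L)
        cols = [f"locus{l}_{ab}" for l in range(L) for ab in ("a", "b")]
        df = pd.DataFrame(flat, columns=cols)
    if pop.mating_type is not None:
        df["mating_type"] = pop.mating_type
    return df
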