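"""Selection trials and the P / g statistics.

One trial is a single generation (two for the diploid perfect-LD comparison)
of reproduction followed by viability selection: each newborn survives with
probability equal to its genotype fitness.  With drift, births continue from
randomly drawn parents until exactly N offspring survive; without drift, the
fixed complementary schedule is executed once and the survivor count is
whatever survival leaves.  Every distinct genotype born — surviving or not —
is added to the tested set.

Across trials two quantities are aggregated:

* ``P`` — the fraction of trials in which the allele that is more mixable
  across the *entire* genotype space increased in frequency more than its
  rival (ties score half a point);
* ``g`` — the mean fraction of the genotype space that was materialized and
  tested.

A fresh calibrated landscape is drawn for every trial, so P estimates the
win probability over both the landscape ensemble and the demographic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import (
    DiploidLandscape,
    FitnessSpec,
    FocalPair,
    HaploidLandscape,
    adjust_all_loci,
    adjust_diploid_pair,
    adjust_haploid_pair,
    build_binary_diploid,
    build_binary_haploid,
    mixability_diploid,
    mixability_haploid,
    pair_index_table,
)
from .popgen import (
    ConfigurationError,
    Population,
    allele_frequency,
    assign_mating_types,
    init_uniform,
    two_clone_start,
)
from .reproduction import (
    HERMAPHRODITE,
    NO_DRIFT,
    SCHEMES,
    TWO_TYPES,
    WITH_DRIFT,
    circular_schedule,
    draw_parent_pairs,
    make_gametes_batch,
    perfect_matching,
    recombine_batch,
)

Landscape = HaploidLandscape | DiploidLandscape


@dataclass(frozen=True)
class TrialConfig:
    """Full parameterization of one simulation cell."""

    N: int = 2000
    num_loci: int = 16
    alleles_per_locus: int = 2
    ploidy: int = 1
    d: float = 1.0112
    r: float = 0.5
    scheme: str = HERMAPHRODITE
    drift: str = WITH_DRIFT
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    start: str = "uniform"  # "uniform" | "clones"
    generations: int = 1
    all_loci: bool = False
    binary_frac_i: float = 0.9
    binary_frac_j: float = 0.89
    diploid_correction: str = "exact_two_allele"
    offspring_cap_factor: int = 1000

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown mating scheme {self.scheme!r}")
        if self.drift not in (WITH_DRIFT, NO_DRIFT):
            raise ConfigurationError(f"unknown drift mode {self.drift!r}")
        if self.generations not in (1, 2):
            raise ConfigurationError("generations must be 1 or 2")
        if self.generations == 2 and self.ploidy != 2:
            raise ConfigurationError(
                "the two-generation protocol applies to the diploid model only"
            )
        if self.start not in ("uniform", "clones"):
            raise ConfigurationError(f"unknown start {self.start!r}")
        if not 0.0 <= self.r <= 0.5:
            raise ConfigurationError("recombination rate must lie in [0, 0.5]")

    @property
    def genotype_space_size(self) -> int:
        n = self.alleles_per_locus
        per_locus = n if self.ploidy == 1 else n * (n + 1) // 2
        return per_locus**self.num_loci

    def focal_pairs(self) -> list[FocalPair]:
        loci = range(self.num_loci) if self.all_loci else (0,)
        return [FocalPair(l, 0, 1, self.d) for l in loci]


@dataclass
class TrialResult:
    """Outcome of one trial at each tracked focal locus."""

    tested_genotypes: int
    births: int
    survivors: int
    focal_loci: tuple[int, ...]
    winners: tuple[str, ...]  # "i" | "j" | "tie" per focal locus
    scores: tuple[float, ...]  # credit earned by the globally more-mixable allele


@dataclass
class ExperimentResult:
    P: float
    g: float
    trials: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    replicates: int = 1
    config: TrialConfig | None = None

    def to_record(self) -> dict:
        rec = {
            "P": self.P,
            "g": self.g,
            "trials": self.trials,
            "replicates": self.replicates,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }
        if self.config is not None:
            c = self.config
            rec = {
                "ploidy": c.ploidy,
                "N": c.N,
                "L": c.num_loci,
                "n": c.alleles_per_locus,
                "d": c.d,
                "r": c.r,
                "sigma": c.fitness.sd,
                "scheme": c.scheme,
                "drift": c.drift,
                "start": c.start,
                "generations": c.generations,
                "mode": c.fitness.mode,
                **rec,
            }
        return rec


def decide_winner(
    init_freq_i: float, init_freq_j: float, final_freq_i: float, final_freq_j: float
) -> str:
    """Which focal allele increased in frequency more; exact equality ties."""
    delta_i = final_freq_i - init_freq_i
    delta_j = final_freq_j - init_freq_j
    if delta_i > delta_j:
        return "i"
    if delta_j > delta_i:
        return "j"
    return "tie"


def make_start_population(cfg: TrialConfig, rng: np.random.Generator) -> Population:
    if cfg.start == "uniform":
        pop = init_uniform(cfg.N, cfg.num_loci, cfg.alleles_per_locus, cfg.ploidy, rng)
    else:
        pop = two_clone_start(cfg.N, cfg.num_loci, cfg.ploidy, cfg.alleles_per_locus)
    if cfg.scheme == TWO_TYPES:
        assign_mating_types(pop, rng)
    return pop


def build_trial_landscape(
    cfg: TrialConfig, rng: np.random.Generator, pop: Population | None = None
) -> Landscape:
    """Draw and calibrate the landscape for one trial.

    Binary landscapes depend on the starting population (all parents must
    have fitness 1), so ``pop`` is required in binary mode.
    """
    L, n = cfg.num_loci, cfg.alleles_per_locus
    if cfg.fitness.mode == "binary":
        if pop is None:
            raise ConfigurationError("binary landscapes require the start population")
        focal = FocalPair(0, 0, 1, cfg.binary_frac_i / cfg.binary_frac_j)
        if cfg.ploidy == 1:
            return build_binary_haploid(
                L, n, pop.genotypes, cfg.binary_frac_i, cfg.binary_frac_j, rng, focal
            )
        table = pair_index_table(n)
        pair_rows = table[pop.genotypes[:, 0, :], pop.genotypes[:, 1, :]]
        return build_binary_diploid(
            L, n, pair_rows, cfg.binary_frac_i, cfg.binary_frac_j, rng, focal
        )
    if cfg.ploidy == 1:
        land = HaploidLandscape.random(L, n, cfg.fitness, rng)
        if cfg.all_loci:
            return adjust_all_loci(land, cfg.focal_pairs())
        return adjust_haploid_pair(land, cfg.focal_pairs()[0], inplace=True)
    if cfg.all_loci:
        raise ConfigurationError("all-loci tracking is a haploid-model feature")
    land = DiploidLandscape.random(L, n, cfg.fitness, rng)
    return adjust_diploid_pair(
        land, cfg.focal_pairs()[0], cfg.diploid_correction, inplace=True
    )


def _offspring_flat(land: Landscape, off: np.ndarray) -> np.ndarray:
    if isinstance(land, HaploidLandscape):
        return land.flat_index(off)
    return land.flat_index(off[:, 0, :], off[:, 1, :])


def _generation_with_drift(
    pop: Population,
    land: Landscape,
    cfg: TrialConfig,
    scheme: str,
    rng: np.random.Generator,
    tested_chunks: list[np.ndarray],
) -> tuple[Population, int]:
    """Generate offspring until exactly N survive; returns (survivors, births).

    Asexual reproduction (r = 0) copies whole parental genotypes, cycling
    through the parents in random order so each is copied once per round.
    """
    N = cfg.N
    cap = cfg.offspring_cap_factor * N
    asexual = cfg.r == 0.0
    survivor_chunks: list[np.ndarray] = []
    have = 0
    births = 0
    asex_buffer = np.empty(0, dtype=np.int64)
    while have < N:
        if births >= cap:
            raise RuntimeError(
                f"offspring cap of {cap} births reached with only {have} survivors; "
                "the landscape is effectively lethal"
            )
        batch = min(int(1.5 * (N - have)) + 32, cap - births)
        if asexual:
            while asex_buffer.size < batch:
                asex_buffer = np.concatenate(
                    [asex_buffer, rng.permutation(pop.size)]
                )
            idx = asex_buffer[:batch]
            asex_buffer = asex_buffer[batch:]
            off = pop.genotypes[idx]
        elif cfg.ploidy == 1:
            i1, i2 = draw_parent_pairs(pop, scheme, batch, rng)
            off, _ = recombine_batch(
                pop.genotypes[i1], pop.genotypes[i2], cfg.r, rng
            )
        else:
            i1, i2 = draw_parent_pairs(pop, scheme, batch, rng)
            g1, _ = make_gametes_batch(pop.genotypes[i1], cfg.r, rng)
            g2, _ = make_gametes_batch(pop.genotypes[i2], cfg.r, rng)
            off = np.stack([g1, g2], axis=1)
        flat = _offspring_flat(land, off)
        alive = rng.random(batch) < land.survival_prob(flat)
        cum = np.cumsum(alive)
        new_total = int(cum[-1]) if batch else 0
        if have + new_total >= N:
            cut = int(np.argmax(cum >= N - have)) + 1
        else:
            cut = batch
        tested_chunks.append(flat[:cut])
        births += cut
        keep = off[:cut][alive[:cut]]
        if keep.size:
            survivor_chunks.append(keep)
        have += int(alive[:cut].sum())
    genos = np.concatenate(survivor_chunks, axis=0)
    return Population(genos, cfg.ploidy, cfg.alleles_per_locus), births


def _generation_no_drift(
    pop: Population,
    land: Landscape,
    cfg: TrialConfig,
    scheme: str,
    rng: np.random.Generator,
    tested_chunks: list[np.ndarray],
) -> tuple[Population, int]:
    """Execute the fixed complementary schedule once; survivor count varies."""
    if cfg.ploidy == 1:
        idx1, idx2 = perfect_matching(pop, scheme, rng)
        off, comp = recombine_batch(
            pop.genotypes[idx1], pop.genotypes[idx2], cfg.r, rng
        )
        offspring = np.concatenate([off, comp], axis=0)
    else:
        pa, pb, slot_a, slot_b = circular_schedule(pop, scheme, rng)
        g, c = make_gametes_batch(pop.genotypes, cfg.r, rng)
        gametes = np.stack([g, c], axis=1)  # (N, slot, L)
        hap_a = gametes[pa, slot_a]
        hap_b = gametes[pb, slot_b]
        offspring = np.stack([hap_a, hap_b], axis=1)
    births = offspring.shape[0]
    flat = _offspring_flat(land, offspring)
    tested_chunks.append(flat)
    alive = rng.random(births) < land.survival_prob(flat)
    genos = offspring[alive]
    return Population(genos, cfg.ploidy, cfg.alleles_per_locus), births


def _more_mixable(land: Landscape, pair: FocalPair) -> str | None:
    mix = mixability_haploid if isinstance(land, HaploidLandscape) else mixability_diploid
    mu_i = mix(land, pair.locus, pair.allele_i)
    mu_j = mix(land, pair.locus, pair.allele_j)
    if mu_i > mu_j:
        return "i"
    if mu_j > mu_i:
        return "j"
    return None


def run_trial(
    cfg: TrialConfig,
    land: Landscape,
    rng: np.random.Generator,
    pop: Population | None = None,
) -> TrialResult:
    """One trial on a given landscape; draws the start population if absent."""
    if pop is None:
        pop = make_start_population(cfg, rng)
    expected_axes = cfg.alleles_per_locus if cfg.ploidy == 1 else (
        cfg.alleles_per_locus * (cfg.alleles_per_locus + 1) // 2
    )
    if land.num_loci != cfg.num_loci or land.fitness.shape[0] != expected_axes:
        raise ConfigurationError("landscape dimensions do not match the config")
    focal = cfg.focal_pairs()
    init_freqs = [
        (
            allele_frequency(pop, p.locus, p.allele_i),
            allele_frequency(pop, p.locus, p.allele_j),
        )
        for p in focal
    ]
    tested_chunks: list[np.ndarray] = []
    births = 0
    current = pop
    for gen in range(cfg.generations):
        # the clone restriction applies to the founding generation only
        scheme = cfg.scheme
        if gen > 0:
            scheme = TWO_TYPES if cfg.scheme == TWO_TYPES else HERMAPHRODITE
            if scheme == TWO_TYPES:
                if current.size % 2:
                    scheme = HERMAPHRODITE
                else:
                    assign_mating_types(current, rng)
        if cfg.drift == WITH_DRIFT:
            current, b = _generation_with_drift(
                current, land, cfg, scheme, rng, tested_chunks
            )
        else:
            current, b = _generation_no_drift(
                current, land, cfg, scheme, rng, tested_chunks
            )
        births += b
        if current.size == 0:
            break
    tested = (
        int(np.unique(np.concatenate(tested_chunks)).size) if tested_chunks else 0
    )
    winners: list[str] = []
    scores: list[float] = []
    for pair, (f0_i, f0_j) in zip(focal, init_freqs):
        if current.size == 0:
            winner = "tie"
        else:
            winner = decide_winner(
                f0_i,
                f0_j,
                allele_frequency(current, pair.locus, pair.allele_i),
                allele_frequency(current, pair.locus, pair.allele_j),
            )
        winners.append(winner)
        more = _more_mixable(land, pair)
        if winner == "tie" or more is None:
            scores.append(0.5)
        else:
            scores.append(1.0 if winner == more else 0.0)
    return TrialResult(
        tested_genotypes=tested,
        births=births,
        survivors=current.size,
        focal_loci=tuple(p.locus for p in focal),
        winners=tuple(winners),
        scores=tuple(scores),
    )


def aggregate(trials: list[TrialResult], genotype_space_size: int) -> ExperimentResult:
    """P = (wins of the globally more-mixable allele + half the ties) over all
    tracked loci and trials; g = mean tested fraction of the genotype space."""
    if not trials:
        raise ValueError("cannot aggregate an empty trial list")
    total_points = sum(sum(t.scores) for t in trials)
    total_cells = sum(len(t.scores) for t in trials)
    P = total_points / total_cells
    g = float(np.mean([t.tested_genotypes / genotype_space_size for t in trials]))
    return ExperimentResult(P=P, g=g, trials=len(trials))


def ci95(p_estimates, method: str = "percentile") -> tuple[float, float]:
    """95% interval over replicate P estimates.

    ``percentile`` (default) takes the empirical 2.5th/97.5th percentiles;
    ``normal`` uses mean +/- 1.96 * SD.
    """
    values = np.asarray(list(p_estimates), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two replicate estimates")
    if method == "percentile":
        lo, hi = np.percentile(values, [2.5, 97.5])
    elif method == "normal":
        m, s = values.mean(), values.std(ddof=1)
        lo, hi = m - 1.96 * s, m + 1.96 * s
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


def run_experiment(
    cfg: TrialConfig, trials: int, rng: np.random.Generator | int
) -> ExperimentResult:
    """Run independent trials (fresh landscape and start population each)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    results = []
    for _ in range(trials):
        pop = make_start_population(cfg, rng)
        land = build_trial_landscape(cfg, rng, pop)
        results.append(run_trial(cfg, land, rng, pop=pop))
    out = aggregate(results, cfg.genotype_space_size)
    out.config = cfg
    return out


def run_replicates(
    cfg: TrialConfig,
    replicates: int,
    trials: int,
    seed: int | np.random.SeedSequence,
    ci_method: str = "percentile",
) -> ExperimentResult:
    """Replicate the experiment and attach a 95% CI over replicate Ps."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(replicates)
    reps = [run_experiment(cfg, trials, np.random.default_rng(c)) for c in children]
    P = float(np.mean([r.P for r in reps]))
    g = float(np.mean([r.g for r in reps]))
    lo, hi = ci95([r.P for r in reps], ci_method) if replicates >= 2 else (P, P)
    return ExperimentResult(
        P=P,
        g=g,
        trials=trials,
        ci_low=lo,
        ci_high=hi,
        replicates=replicates,
        config=cfg,
    )
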