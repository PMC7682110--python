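# Methods

`mixsim` simulates a single generation (two in one diploid protocol) of
sexual or asexual reproduction followed by viability selection on an
epistatic fitness landscape, and measures how reliably selection identifies
the allele that is *more mixable* — the allele with the higher unweighted
mean fitness over the entire space of possible genotypes — while only a
small random fraction of that space is ever materialized and tested.

## Model

**Genotypes and fitness.** A haploid genotype is a tuple of `L` allele
indices, one per locus, with `n` alleles per locus; there are `n^L` possible
genotypes. A diploid genotype carries an unordered allele pair at each locus
(no position effects), giving `(n(n+1)/2)^L` genotypes. Fitness `w` in
`[0, 1]` is the probability that a newborn of that genotype survives;
fertility is not genetic.

**Fitness distributions.** Continuous landscapes draw every genotype's
fitness iid from Normal(E, σ) with out-of-`[0, 1]` draws rejected and
redrawn (a doubly truncated normal; at the defaults E = 0.7, σ = 0.15 the
realised moments are 0.6917 and 0.1412). Binary landscapes assign fitness 0
or 1, with the fraction of fitness-1 genotypes among the carriers of each
focal allele set exactly to a target (e.g. 0.9 vs 0.87).

**Mixability and calibration.** The mixability of allele `a` at locus `l`
is the mean fitness of all genotypes carrying `a` there, *unweighted* by
genotype frequencies. Each trial draws a fresh landscape and rescales the
carriers of two focal alleles — multiply the carriers of allele `î` by
`sqrt(d·μ̃_ĵ/μ̃_î)` and those of `ĵ` by the reciprocal — so that the
mixability ratio `μ_î/μ_ĵ` equals a chosen `d` exactly. In the two-allele
diploid model the heterozygote class is shared by both carriers, so the two
homozygote-like classes are rescaled until their fitness-sum ratio is
`2d − 1` exactly, which puts the carrier-level ratio at `d` up to the
sampling fluctuation of the heterozygote sum (the heterozygote entries are
untouched). A `large_n` variant applies the plain ratio `d`, accurate when
the shared class is a vanishing fraction of carriers. Rescaling can push a
fitness value slightly above 1 (about 0.1% of entries at `d ≈ 1.01`, up to
~2% at `d ≈ 1.11`); survival uses `min(w, 1)` and the capped count is
logged. Allowing the overshoot preserves the exact-ratio identity, which the
tests check to 1e−12.

**Reproduction.** Recombination follows the Poisson model: the offspring
takes locus 1 from a uniformly chosen parent (haploid) or parental
haplotype (diploid meiosis), and the source switches between neighboring
loci with probability `r ≤ 0.5` independently per interval. `r = 0.5` is
free recombination; `r = 0` is the asexual limit, implemented as clonal
copying of whole parental genotypes. Asexual copying cycles through the
parents in randomized rounds (each parent copied once per round) rather
than sampling parents with replacement; this removes fertility noise from
the asexual comparison and makes the binary asexual case an exact tie, while
survival noise — the quantity of interest — is untouched. Every
recombination also defines a complementary product (the locus-wise opposite
source choice), so a mating can transmit each parental allele exactly once.

**Mating schemes.** Default is selfing-capable hermaphrodites: both parents
drawn uniformly with replacement (self-pairing probability `1/N`). The
two-mating-type scheme labels half the population type 1 and half type 2 and
draws one parent from each. Clone-restricted mating (used with the
perfect-LD start) draws one parent from each of the two founding clones.

**Drift modes.** With drift, offspring are generated until exactly `N`
survive; the number of distinct genotypes born (survivors or not) is
recorded as the *tested set*. Without drift, each haploid parent enters
exactly one mating that produces the two complementary offspring (each
diploid parent enters two matings, arranged in a random circle with each
neighbor, donating its two complementary gametes one to each); every
parental allele is transmitted exactly once, all `N` offspring are exposed
to survival, and the survivor count is whatever remains — constant
population size is given up to remove fertility and transmission noise.

**Starts.** The uniform start deals alleles from an exactly balanced store
(every allele at frequency `1/n` exactly, independently permuted per
locus). The perfect-LD start stamps `N/2` copies each of the clones
`(0,…,0)` and `(1,…,1)` (homozygous in diploids), so that sexual shuffling,
not initial variation, creates new combinations.

**Statistics.** After the final generation the winner at a focal locus is
the allele whose frequency rose more relative to the start (exact equality
is a tie). `P` is the fraction of trials won by the globally more-mixable
allele, ties counting half; in all-loci mode wins are summed over loci and
divided by `L · trials`. `g` is the across-trials mean fraction of genotype
space tested. Replicated experiments attach a 95% interval over replicate
`P` estimates — empirical 2.5/97.5 percentiles by default (the method is
not prescribed by the protocol; a normal-approximation variant is
available).

**Two-generation diploid protocol.** From homozygous clones every between-
clone mating yields the same fully heterozygous F1, so one sexual
generation cannot separate the alleles. The comparison therefore runs two
generations — the first under the clone restriction, the second as free
random mating among the survivors — and compares the second generation's
survivors with the starting population. Whether the second generation keeps
any mating restriction is not specified by the protocol; free mating is the
simplest choice.

**Closed-form theory.** Calibration multiplies one allele's fitness
distribution by ~`sqrt(d)` and the other's by ~`1/sqrt(d)`, so the carrier
distributions are `Normal(E√d, σ√d)` and `Normal(E/√d, σ/√d)` (with `2d − 1`
in place of `d` for the diploid homozygote comparison, the heterozygote
cancelling from both sides). The asexual correct-evaluation probability
compares one draw from each distribution; the sexual one compares sample
means of `M` draws, which by the CLT is

    P(A > B) = Φ( (E_X − E_Y) / sqrt((σ_X² + σ_Y²)/M) ).

`M` defaults to the expected carrier count `N·ploidy/n` (1000 at
N = 2000, n = 2, haploid): this reproduces the published sexual value 0.88
at `d = 1.0112`, whereas `M = N` does not. The published asexual anchors
(0.5064/0.5691/0.6327 haploid; 0.5236/0.6393/0.6918 diploid) are not
exactly reproduced by this formula with either plain or truncated moments
(we obtain e.g. 0.5147 and 0.5291 at `d = 1.0112`); the package reports its
computed values alongside rather than forcing agreement, and the simulated
asexual P (0.636 at `d = 1.1111`, L = 12) in fact matches our computed
0.6356 closely. An optional flag substitutes the exact truncated-normal
moments for `(E, σ)` before scaling.

## Parameters that matter

| parameter | meaning | default | note |
|---|---|---|---|
| `N` | population size (survivors per generation with drift) | 2000 | sexual `P` grows with `N`; asexual does not |
| `L` | loci | 16 | genotype space `n^L`; `g` falls roughly as `births/n^L` |
| `n` | alleles per locus | 2 | diploid advantage shrinks as `n` grows |
| `d` | target mixability ratio | 1.0112 | panel grid 1.0112…1.1111 (= 0.9/0.89 … 0.9/0.81) |
| `r` | per-interval crossover probability | 0.5 | 0 = asex, 0.5 = free recombination |
| `E, σ` | fitness distribution | 0.7, 0.15 | larger σ hurts asexual `P` far more than sexual |
| trials | Monte-Carlo repetitions per cell | 100 | the published protocol; CIs use 80 replicates of 100 |

## Numerical choices and degenerate inputs

- Rejection sampling is capped at 10⁶ redraws; an acceptance region with
  negligible mass raises an error instead of hanging.
- With-drift generation loops are capped at `1000·N` births; an effectively
  lethal landscape raises an error.
- Offspring are generated in vectorized batches but counted sequentially:
  the tested set and birth count include exactly the births up to the one
  that produced the `N`-th survivor, as in a strictly sequential process.
- Diploid pair keys store `min(i, j)` first; lookups of `(i, j)` and
  `(j, i)` are the identical entry by construction.
- Zero-mixability focal alleles, non-divisible store sizes, odd populations
  under pairing schemes, and `2d − 1 ≤ 0` all raise typed errors.
- Binary fills are infeasible when the starting population's genotypes
  (which must all have fitness 1) crowd out the zeros a target fraction
  requires; at `N = 2000`, `n = 2` this needs roughly `L ≥ 11` (haploid).
  The shared heterozygote class is filled at the mean of the two target
  rates, then each exclusive carrier class is topped up to its own target.
- Per-cell sweep streams are spawned from `SeedSequence(master, cell)`, so
  identical configurations reproduce byte-identically and cells can be
  re-run independently.

## What the generator emulates — and what it does not

The synthetic landscapes reproduce the study conditions exactly: iid
(truncated-normal or binary) genotype fitnesses with a calibrated
mixability gap at one focal locus pair. Real fitness landscapes are not iid
across genotypes — they carry correlated, structured epistasis, linkage
maps with interference, mutation, and multigenerational dynamics, none of
which are modelled here. Passing tests therefore demonstrate the
randomization mechanism under the stated statistical conditions, not the
magnitude of the effect in any real genome. Scope is deliberately limited
to viability selection over one (or two) generations: no fertility
selection, position effects, mutation, age or spatial structure, or
modifier-gene evolution.

## Known limitations

- `P` and `g` are Monte-Carlo estimates; at the published 100-trial
  protocol `P` carries a binomial standard error of ≈ 0.05 near 0.6.
  Headline comparisons in the test suite use 100–200 trials with bands that
  account for this.
- The no-drift diploid circular pairing is one of several schedules
  satisfying "each parent in exactly two matings, each allele transmitted
  once"; the choice is documented here because the protocol does not pin it
  down.
- The fitness cap `min(w, 1)` makes the *realised* survival-probability
  ratio marginally smaller than `d` (worst case ~2% of entries capped at
  `d = 1.1111`); the calibration identity itself is exact pre-cap.
- Full landscapes are materialized in memory, which is what keeps trials
  fast but limits practical sizes to roughly `n^L ≤ 10^7` haploid
  (`3^L ≤ 10^7` diploid at `n = 2`).
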