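# mixsim

Forward-time simulation of **selection for allele mixability** under sexual
recombination, in multilocus haploid and diploid populations.

## The problem

In a finite population only a tiny fraction of the `n^L` possible multilocus
genotypes ever exists. Sexual recombination continually re-randomizes which
combinations are formed, so the genotypes carrying a given allele are an
essentially unbiased sample of the whole space. The question this package
quantifies: if allele `î` is more *mixable* than allele `ĵ` — i.e. its
unweighted mean fitness over **all** possible genotypes,

    μ_î = (1 / n^(L−1)) · Σ w_{î, i₂, …, i_L},

exceeds `μ_ĵ` by a factor `d = μ_î/μ_ĵ` — how often does one generation of
reproduction and viability selection, which tests only a fraction `g` of
genotype space, move `î`'s frequency up more than `ĵ`'s? That success rate
over independent trials is `P`. The asexual contrast (clonal copying, no
recombination) isolates recombination as the source of the effect, and a
closed-form CLT calculation gives the corresponding theoretical win
probabilities: selection under sex compares *sample means* of many fitness
draws per allele, while the clonal comparison rests on a single draw each.

Each trial draws a fresh epistatic landscape — genotype fitnesses iid from a
`[0, 1]`-truncated Normal(0.7, 0.15), or binary 0/1 — and rescales the focal
alleles' carriers so the mixability ratio equals `d` exactly (in the
two-allele diploid model the homozygote classes are set to the `2d − 1`
sum ratio that the shared heterozygote forces). Mating schemes (selfing
hermaphrodites, two mating types, clone-restricted), drift-free
complementary-transmission schedules, uniform and two-clone starts, and the
Poisson crossover model (`r = 0` asex … `r = 0.5` free recombination) are
all supported. See `docs/methods.md` for the model in full.

## Worked example

One cell of the standard haploid experiment — `N = 2000`, `L = 16` loci,
`n = 2` alleles, mixability ratio `d = 1.0112`, free recombination, 100
trials:

```bash
$ mixsim simulate --N 2000 --L 16 --d 1.0112 --trials 100 --seed 7
ploidy,N,L,n,d,r,sigma,scheme,drift,start,generations,mode,P,g,trials,...
1,2000,16,2,1.0112,0.5,0.15,hermaphrodite_selfing,with_drift,uniform,1,continuous,0.55,0.0431...,100,...
```

`P = 0.55` (standard error ≈ 0.05 at 100 trials): even at this nearly
invisible mixability gap of 1.1%, selection picks the globally more-mixable
allele better than chance — while `g = 0.043` says only 4.3% of the 65 536
possible genotypes were ever born and tested. The matching closed forms:

```bash
$ mixsim theory --d 1.0112,1.0588,1.1111 --N 2000 --ploidy 1
d,ploidy,samples_per_allele,sex_P,asex_P
1.0112,1,1000,0.877421217751889,0.5146585197183429
1.0588,1,1000,0.9999999987240744,0.5747230397504961
1.1111,1,1000,1.0,0.6356434227999743
```

With ~1000 carriers per allele the CLT sexual probability is 0.88 already at
`d = 1.0112`, while a clonal population — one fitness draw per lineage —
barely beats a coin flip (0.51). Sweeps over the full experimental grids
(loci, `d`, recombination rate, population size, fitness variance, binary
landscapes, drift-free schedules) are available as presets:

```bash
mixsim sweep --preset fig3 --trials 25 --seed 0 --out fig3.csv
```

The library API mirrors the CLI: `HaploidLandscape.random` +
`adjust_haploid_pair` build calibrated landscapes, `run_experiment` /
`run_replicates` return `P`, `g` and confidence intervals, and
`sex_theoretical_P` / `asex_theoretical_P` evaluate the closed forms.

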