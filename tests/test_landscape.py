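"""Landscape construction, mixability, and exact-ratio calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mixsim import (
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
    read_landscape,
    sample_truncated_fitness,
    write_landscape,
)
from mixsim.landscape import LandscapeError, pair_index_table


class TestTruncatedSampling:
    def test_rejection_keeps_bounds(self, rng):
        values = sample_truncated_fitness(FitnessSpec(), 50_000, rng)
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_moments_match_truncated_normal(self, rng):
        """Sample mean/sd agree with the closed-form doubly truncated
        normal moments (0.6917, 0.1412) at E=0.7, sigma=0.15 on [0, 1]."""
        values = sample_truncated_fitness(FitnessSpec(), 400_000, rng)
        a, b = (0 - 0.7) / 0.15, (1 - 0.7) / 0.15
        m, v = stats.truncnorm.stats(a, b, loc=0.7, scale=0.15, moments="mv")
        assert values.mean() == pytest.approx(float(m), abs=3e-3)
        assert values.std() == pytest.approx(float(np.sqrt(v)), abs=3e-3)
        assert float(m) == pytest.approx(0.6917, abs=1e-4)
        assert float(np.sqrt(v)) == pytest.approx(0.1412, abs=1e-4)

    def test_unbounded_spec_is_plain_normal(self, rng):
        spec = FitnessSpec(lo=-np.inf, hi=np.inf)
        values = sample_truncated_fitness(spec, 200_000, rng)
        assert values.mean() == pytest.approx(0.7, abs=2e-3)
        assert values.std() == pytest.approx(0.15, abs=2e-3)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            FitnessSpec(sd=-0.1)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            FitnessSpec(lo=1.0, hi=0.0)


class TestHaploidMixability:
    def test_constant_landscape(self):
        land = HaploidLandscape(3, 2, np.full((2, 2, 2), 0.3))
        for locus in range(3):
            for allele in range(2):
                assert mixability_haploid(land, locus, allele) == pytest.approx(0.3)

    def test_two_term_averages(self, toy_haploid):
        assert mixability_haploid(toy_haploid, 0, 0) == pytest.approx(0.5)
        assert mixability_haploid(toy_haploid, 0, 1) == pytest.approx(0.9)
        assert mixability_haploid(toy_haploid, 1, 0) == pytest.approx(0.6)
        assert mixability_haploid(toy_haploid, 1, 1) == pytest.approx(0.8)

    def test_index_errors(self, toy_haploid):
        with pytest.raises(IndexError):
            mixability_haploid(toy_haploid, 2, 0)
        with pytest.raises(IndexError):
            mixability_haploid(toy_haploid, 0, 5)


class TestAdjustHaploid:
    def test_toy_exact_values(self, toy_haploid):
        """d = 10/9 for allele 0 over allele 1 scales by sqrt(2) exactly."""
        adj = adjust_haploid_pair(toy_haploid, FocalPair(0, 0, 1, 10 / 9))
        factor = np.sqrt((10 / 9) * 0.9 / 0.5)
        assert factor == pytest.approx(np.sqrt(2))
        assert mixability_haploid(adj, 0, 0) == pytest.approx(0.70711, abs=1e-5)
        assert mixability_haploid(adj, 0, 1) == pytest.approx(0.63640, abs=1e-5)
        ratio = mixability_haploid(adj, 0, 0) / mixability_haploid(adj, 0, 1)
        assert ratio == pytest.approx(10 / 9, rel=1e-14)

    def test_identity_when_balanced(self):
        land = HaploidLandscape(2, 2, np.array([[0.5, 0.7], [0.7, 0.5]]))
        adj = adjust_haploid_pair(land, FocalPair(0, 0, 1, 1.0))
        np.testing.assert_array_equal(adj.fitness, land.fitness)

    def test_untouched_entries_bitwise(self, rng):
        land = HaploidLandscape.random(3, 3, FitnessSpec(), rng)
        before = land.fitness.copy()
        adj = adjust_haploid_pair(land, FocalPair(1, 0, 1, 1.05))
        # allele 2 at locus 1 carries neither focal allele
        np.testing.assert_array_equal(adj.fitness[:, 2, :], before[:, 2, :])
        assert not np.array_equal(adj.fitness[:, 0, :], before[:, 0, :])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), d=st.floats(1.0, 1.12))
    def test_ratio_exact_over_random_landscapes(self, seed, d):
        rng = np.random.default_rng(seed)
        land = HaploidLandscape.random(4, 2, FitnessSpec(), rng)
        adj = adjust_haploid_pair(land, FocalPair(0, 0, 1, d))
        ratio = mixability_haploid(adj, 0, 0) / mixability_haploid(adj, 0, 1)
        assert abs(ratio - d) <= 1e-12 * d

    def test_degenerate_landscape_rejected(self):
        land = HaploidLandscape(1, 2, np.array([0.5, 0.0]))
        with pytest.raises(LandscapeError):
            adjust_haploid_pair(land, FocalPair(0, 0, 1, 1.05))


class TestAdjustAllLoci:
    def test_single_locus_matches_pairwise(self, rng):
        land = HaploidLandscape.random(1, 2, FitnessSpec(), rng)
        pair = FocalPair(0, 0, 1, 1.05)
        seq = adjust_all_loci(land, [pair])
        one = adjust_haploid_pair(land, pair)
        np.testing.assert_allclose(seq.fitness, one.fitness)

    def test_last_locus_exact_first_approximate(self, rng):
        land = HaploidLandscape.random(2, 2, FitnessSpec(), rng)
        pairs = [FocalPair(l, 0, 1, 1.05) for l in range(2)]
        adj = adjust_all_loci(land, pairs)
        r_last = mixability_haploid(adj, 1, 0) / mixability_haploid(adj, 1, 1)
        r_first = mixability_haploid(adj, 0, 0) / mixability_haploid(adj, 0, 1)
        assert r_last == pytest.approx(1.05, rel=1e-13)
        assert r_first == pytest.approx(1.05, rel=0.05)

    def test_duplicate_locus_rejected(self, rng):
        land = HaploidLandscape.random(2, 2, FitnessSpec(), rng)
        with pytest.raises(ValueError):
            adjust_all_loci(land, [FocalPair(0, 0, 1, 1.1)] * 2)


class TestDiploidLandscape:
    def test_pair_symmetry(self, rng):
        land = DiploidLandscape.random(2, 3, FitnessSpec(), rng)
        for i in range(3):
            for j in range(3):
                assert land.lookup([(i, j), (0, 0)]) == land.lookup([(j, i), (0, 0)])

    def test_constant_mixability(self):
        land = DiploidLandscape(2, 2, np.full((3, 3), 0.4))
        assert mixability_diploid(land, 0, 0) == pytest.approx(0.4)
        assert mixability_diploid(land, 1, 1) == pytest.approx(0.4)

    def test_single_locus_carrier_sums(self):
        # w(ii)=0.6, w(ij)=0.7, w(jj)=0.6: both carrier rows sum to 1.3
        land = DiploidLandscape(1, 2, np.array([0.6, 0.7, 0.6]))
        assert mixability_diploid(land, 0, 0) == pytest.approx(1.3 / 2)
        assert mixability_diploid(land, 0, 1) == pytest.approx(1.3 / 2)

    def test_entry_count(self):
        land = DiploidLandscape.random(
            3, 3, FitnessSpec(), np.random.default_rng(0)
        )
        assert land.fitness.size == 6**3


class TestAdjustDiploid:
    def test_toy_exact_values(self):
        land = DiploidLandscape(1, 2, np.array([0.6, 0.7, 0.6]))
        adj = adjust_diploid_pair(land, FocalPair(0, 0, 1, 1.05))
        s = np.sqrt(1.1)
        assert adj.fitness[0] == pytest.approx(0.6 * s, abs=1e-5)
        assert adj.fitness[1] == pytest.approx(0.7)  # heterozygote untouched
        assert adj.fitness[2] == pytest.approx(0.6 / s, abs=1e-5)
        assert adj.fitness[0] / adj.fitness[2] == pytest.approx(1.1, rel=1e-14)
        carrier_ratio = (adj.fitness[0] + 0.7) / (0.7 + adj.fitness[2])
        assert carrier_ratio == pytest.approx(1.0450, abs=1e-4)

    def test_identity_at_d_one_with_equal_sums(self):
        land = DiploidLandscape(1, 2, np.array([0.6, 0.7, 0.6]))
        adj = adjust_diploid_pair(land, FocalPair(0, 0, 1, 1.0))
        np.testing.assert_array_equal(adj.fitness, land.fitness)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), d=st.floats(1.0, 1.12))
    def test_homozygote_ratio_and_het_invariance(self, seed, d):
        rng = np.random.default_rng(seed)
        land = DiploidLandscape.random(2, 2, FitnessSpec(), rng)
        het_before = land.fitness[1, :].copy()
        adj = adjust_diploid_pair(land, FocalPair(0, 0, 1, d))
        ratio = adj.fitness[0, :].sum() / adj.fitness[2, :].sum()
        assert ratio == pytest.approx(2 * d - 1, rel=1e-13)
        np.testing.assert_array_equal(adj.fitness[1, :], het_before)

    def test_carrier_ratio_close_to_d(self, rng):
        land = DiploidLandscape.random(3, 2, FitnessSpec(), rng)
        adj = adjust_diploid_pair(land, FocalPair(0, 0, 1, 1.08))
        ratio = mixability_diploid(adj, 0, 0) / mixability_diploid(adj, 0, 1)
        assert ratio == pytest.approx(1.08, rel=0.02)

    def test_invalid_ratio_rejected(self, rng):
        land = DiploidLandscape.random(1, 2, FitnessSpec(), rng)
        with pytest.raises(LandscapeError):
            adjust_diploid_pair(land, FocalPair(0, 0, 1, 0.4))

    def test_large_n_mode(self, rng):
        land = DiploidLandscape.random(2, 6, FitnessSpec(), rng)
        het_before = land.lookup([(0, 1), (2, 2)])
        adj = adjust_diploid_pair(land, FocalPair(0, 0, 1, 1.05), "large_n")
        ratio = mixability_diploid(adj, 0, 0) / mixability_diploid(adj, 0, 1)
        assert ratio == pytest.approx(1.05, rel=0.02)
        assert adj.lookup([(0, 1), (2, 2)]) == het_before


class TestBinaryLandscapes:
    def _parents(self, rng, L, k=40):
        return rng.integers(0, 2, size=(k, L))

    def test_haploid_fractions_and_parent_viability(self, rng):
        L = 12
        parents = self._parents(rng, L)
        land = build_binary_haploid(L, 2, parents, 0.9, 0.87, rng)
        assert set(np.unique(land.fitness)) <= {0.0, 1.0}
        flat = land.fitness.reshape(-1)
        assert (flat[land.flat_index(parents)] == 1.0).all()
        mu_i = mixability_haploid(land, 0, 0)
        mu_j = mixability_haploid(land, 0, 1)
        carriers = 2 ** (L - 1)
        assert mu_i == pytest.approx(0.9, abs=1 / carriers)
        assert mu_j == pytest.approx(0.87, abs=1 / carriers)
        assert mu_i / mu_j == pytest.approx(0.9 / 0.87, abs=2 / carriers)

    def test_all_ones_when_fractions_one(self, rng):
        land = build_binary_haploid(6, 2, self._parents(rng, 6, 10), 1.0, 1.0, rng)
        assert (land.fitness == 1.0).all()

    def test_infeasible_when_parents_crowd_out_zeros(self, rng):
        # 4 loci, 2 alleles: 16 genotypes; 0.5 fraction needs 4 ones per
        # carrier class but most genotypes are parents
        parents = np.array(np.meshgrid(*[[0, 1]] * 4)).T.reshape(-1, 4)
        with pytest.raises(LandscapeError):
            build_binary_haploid(4, 2, parents, 0.5, 0.5, rng)

    def test_diploid_fractions_shared_heterozygote(self, rng):
        L = 8
        hapa = rng.integers(0, 2, size=(30, L))
        hapb = rng.integers(0, 2, size=(30, L))
        table = pair_index_table(2)
        pair_rows = table[hapa, hapb]
        land = build_binary_diploid(L, 2, pair_rows, 0.9, 0.85, rng)
        flat = land.fitness.reshape(-1)
        idx = np.ravel_multi_index(tuple(pair_rows[:, l] for l in range(L)), (3,) * L)
        assert (flat[idx] == 1.0).all()
        carriers = 2 * 3 ** (L - 1)
        assert mixability_diploid(land, 0, 0) == pytest.approx(0.9, abs=2 / carriers)
        assert mixability_diploid(land, 0, 1) == pytest.approx(0.85, abs=2 / carriers)


class TestLandscapeIO:
    def test_haploid_roundtrip(self, tmp_path, rng):
        land = HaploidLandscape.random(3, 2, FitnessSpec(), rng)
        path = tmp_path / "land.tsv"
        write_landscape(land, path)
        back = read_landscape(path)
        assert isinstance(back, HaploidLandscape)
        np.testing.assert_allclose(back.fitness, land.fitness)

    def test_diploid_roundtrip(self, tmp_path, rng):
        land = DiploidLandscape.random(2, 2, FitnessSpec(), rng)
        path = tmp_path / "dip.tsv"
        write_landscape(land, path)
        back = read_landscape(path)
        assert isinstance(back, DiploidLandscape)
        np.testing.assert_allclose(back.fitness, land.fitness)
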