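from itertools import combinations

import numpy as np
import pytest

import bridgehead as bh
from bridgehead.genotype_io import PopulationMap
from bridgehead.popgen_stats import (
    StatCatalogue,
    build_scopes,
    summary_values,
    summary_values_blockwise,
)

from conftest import make_matrix


def pi_by_pair_enumeration(haploids):
    """Oracle: fraction of differing pairs over all haploid pairs."""
    pairs = list(combinations(haploids, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


class TestSitePi:
    def test_monomorphic_is_zero(self):
        assert bh.site_pi(np.array([0, 0, 0])) == 0.0
        assert bh.site_pi(np.array([2, 2])) == 0.0

    @pytest.mark.parametrize(
        "dosages,haploids",
        [
            (np.array([1, 1]), [0, 1, 0, 1]),  # counts (2,2), n=4 -> 2/3
            (np.array([0, 1]), [0, 0, 0, 1]),  # counts (3,1), n=4 -> 1/2
            (np.array([2, 1, 0]), [1, 1, 1, 0, 0, 0]),
        ],
    )
    def test_matches_pair_enumeration(self, dosages, haploids):
        assert bh.site_pi(dosages) == pytest.approx(pi_by_pair_enumeration(haploids))

    def test_random_sites_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_dip = rng.integers(1, 7)
            dosages = rng.integers(0, 3, n_dip)
            haploids = []
            for d in dosages:
                haploids += [1] * d + [0] * (2 - d)
            if len(haploids) < 2:
                continue
            assert bh.site_pi(dosages) == pytest.approx(
                pi_by_pair_enumeration(haploids)
            )

    def test_insufficient_calls_error(self):
        with pytest.raises(ValueError):
            bh.site_pi(np.array([bh.MISSING, bh.MISSING]))


class TestPopulationPiGenome:
    def _pm(self, samples, pop="p1"):
        return PopulationMap({s: (pop, "UK") for s in samples})

    def test_all_invariant_toy_is_zero(self):
        gm = make_matrix(np.zeros((4, 5)), kind="invariant")
        res = bh.population_pi_genome(gm, self._pm(gm.samples), "p1")
        assert res.pi_genome == 0.0

    def test_three_site_hand_mean(self):
        # sites: (1,1) -> 2/3; (0,0) -> 0; (2,0) -> 2*2*2/(4*3) = 2/3
        calls = np.array([[1, 0, 2], [1, 0, 0]])
        gm = make_matrix(calls)
        res = bh.population_pi_genome(gm, self._pm(gm.samples), "p1")
        assert res.pi_genome == pytest.approx((2 / 3 + 0 + 2 / 3) / 3)
        assert len(res.per_site) == 3

    def test_empty_population_error(self):
        gm = make_matrix(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            bh.population_pi_genome(gm, self._pm(gm.samples), "nope")


def wc84_anova_oracle(calls_a, calls_b):
    """Independently coded WC84 theta via literal nested-ANOVA sums.

    Genotypes are expanded into gametes (allele indicators) and the
    sums of squares for populations, individuals-in-populations and
    gametes-in-individuals are accumulated directly from the data.
    Variance components follow from the standard expected-mean-square
    relations of the two-level nested random-effects ANOVA; theta is the
    multi-locus ratio of summed components.  No closed-form shortcut from
    the estimator under test is reused.
    """

    def locus_components(groups):
        # groups: list of 1-D dosage arrays (complete data)
        n_i = np.array([float(g.size) for g in groups])  # individuals
        n_tot = n_i.sum()
        r = len(groups)
        gam_means = [g / 2.0 for g in groups]  # per-individual allele freq
        pop_means = np.array([gm.mean() for gm in gam_means])
        grand = (n_i * pop_means).sum() / n_tot
        ssg = sum(((g == 1).sum()) * 0.5 for g in groups)  # within-individual
        ssi = 2.0 * sum(
            ((gm - pm_) ** 2).sum() for gm, pm_ in zip(gam_means, pop_means)
        )
        ssp = 2.0 * (n_i * (pop_means - grand) ** 2).sum()
        msg = ssg / n_tot
        msi = ssi / (n_tot - r)
        msp = ssp / (r - 1)
        nc = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
        sig_g = msg
        sig_i = (msi - msg) / 2.0
        sig_p = (msp - msi) / (2.0 * nc)
        return sig_p, sig_i, sig_g

    num_sum, den_sum = 0.0, 0.0
    for j in range(calls_a.shape[1]):
        ga = calls_a[:, j][calls_a[:, j] != bh.MISSING]
        gb = calls_b[:, j][calls_b[:, j] != bh.MISSING]
        if ga.size < 1 or gb.size < 1 or ga.size + gb.size < 3:
            continue
        sig_p, sig_i, sig_g = locus_components([ga, gb])
        num_sum += sig_p
        den_sum += sig_p + sig_i + sig_g
    if den_sum == 0.0:
        return np.nan
    return num_sum / den_sum


class TestFst:
    def _two_pops(self, calls):
        n = calls.shape[0] // 2
        samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        gm = make_matrix(calls, samples=samples)
        pm = PopulationMap(
            {s: ("pa", "GA") if s.startswith("A") else ("pb", "GB") for s in samples}
        )
        return gm, pm

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, 500)
        calls = rng.binomial(2, p, size=(60, 500)).astype(np.int8)
        gm, pm = self._two_pops(calls)
        assert abs(bh.fst_pairwise(gm, pm, "GA", "GB")) < 0.02

    def test_fixed_difference_is_one(self):
        calls = np.vstack([np.zeros((10, 50)), np.full((10, 50), 2)]).astype(np.int8)
        gm, pm = self._two_pops(calls)
        assert bh.fst_pairwise(gm, pm, "GA", "GB") == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        from bridgehead.popgen_stats import _fst_wc84

        for seed in range(5):
            r = np.random.default_rng(seed)
            pa = r.uniform(0.1, 0.9, 80)
            pb = np.clip(pa + r.normal(0, 0.25, 80), 0.01, 0.99)
            ca = r.binomial(2, pa, size=(15, 80)).astype(np.int8)
            cb = r.binomial(2, pb, size=(12, 80)).astype(np.int8)
            ours = _fst_wc84(ca, cb)
            oracle = wc84_anova_oracle(ca, cb)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_hudson_agrees_in_sign_and_scale(self):
        rng = np.random.default_rng(3)
        pa = rng.uniform(0.1, 0.9, 300)
        pb = np.clip(pa + rng.normal(0, 0.3, 300), 0.01, 0.99)
        ca = rng.binomial(2, pa, size=(20, 300)).astype(np.int8)
        cb = rng.binomial(2, pb, size=(20, 300)).astype(np.int8)
        gm, pm = self._two_pops(np.vstack([ca, cb]))
        wc = bh.fst_pairwise(gm, pm, "GA", "GB", estimator="WC84")
        hu = bh.fst_pairwise(gm, pm, "GA", "GB", estimator="hudson")
        assert wc > 0 and hu > 0
        assert abs(wc - hu) < 0.1

    def test_self_comparison_near_zero(self):
        # one population duplicated as two groups
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, 500)
        calls = rng.binomial(2, p, size=(60, 500)).astype(np.int8)
        gm, pm = self._two_pops(calls)
        assert abs(bh.fst_pairwise(gm, pm, "GA", "GB")) < 0.02


class TestSummaryVector:
    def _fixture(self, seed=0, missing=0.1):
        gm, pm = bh.generate_population_fixture(
            6,
            8,
            0.1,
            seed=seed,
            n_snps=150,
            missing_rate=missing,
            group_names=["ALE", "AKBC", "COAST", "NORTH", "SOUTH", "UK"],
        )
        return gm, pm

    def test_vector_length_formula(self):
        gm, pm = self._fixture()
        vec = bh.summary_vector(gm, pm)
        n_pop, n_pair = 4, 2
        assert len(vec) == 6 * n_pop + 15 * n_pair + 3 * n_pop + 3 * n_pair

    def test_deterministic_and_permutation_invariant(self):
        gm, pm = self._fixture()
        v1 = bh.summary_vector(gm, pm)
        v2 = bh.summary_vector(gm, pm)
        np.testing.assert_array_equal(v1.values, v2.values)
        rng = np.random.default_rng(5)
        perm = rng.permutation(gm.n_samples)
        gm_p = bh.GenotypeMatrix(
            [gm.samples[i] for i in perm], gm.sites, gm.calls[perm]
        )
        v3 = bh.summary_vector(gm_p, pm)
        assert v3.names == v1.names
        np.testing.assert_allclose(v3.values, v1.values, rtol=1e-12)

    def test_vectorised_equals_blockwise(self):
        gm, pm = self._fixture(seed=7, missing=0.25)
        names, sidx, gnames, gidx = build_scopes(gm.samples, pm, None)
        cat = StatCatalogue()
        fast = summary_values(gm.calls, sidx, gidx, cat)
        slow = summary_values_blockwise(gm.calls, sidx, gidx, cat)
        np.testing.assert_allclose(fast, slow, rtol=1e-12, equal_nan=True)
        cat_h = StatCatalogue(fst_estimator="hudson")
        np.testing.assert_allclose(
            summary_values(gm.calls, sidx, gidx, cat_h),
            summary_values_blockwise(gm.calls, sidx, gidx, cat_h),
            rtol=1e-12,
            equal_nan=True,
        )

    def test_empty_scope_yields_sentinels_not_drops(self):
        gm, pm0 = self._fixture()
        # popmap mentioning a group with no samples in the matrix
        entries = dict(pm0.items())
        entries["ghost"] = ("nowhere", "OTHER")
        pm = PopulationMap(entries)
        with pytest.warns(UserWarning, match="no samples"):
            vec = bh.summary_vector(gm, pm)
        assert any(n.startswith("pop:OTHER:") for n in vec.names)
        other_vals = [v for n, v in zip(vec.names, vec.values) if ":OTHER:" in n]
        assert np.isnan(other_vals).all()
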