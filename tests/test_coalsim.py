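import numpy as np
import pytest
from scipy import stats

import bridgehead as bh
from bridgehead.coalsim import (
    CoalescentTree,
    build_events,
    pair_haploids,
    simulate_calls,
)


def _single_pop_params(ne=1000.0, **over):
    base = dict(
        ne={g: ne for g in ("ALE", "AKBC", "COAST", "NORTH", "SOUTH", "UK", "ANC")},
        t0a=100.0,
        wave_times=(),
        wave_props=(),
        splits={"t1": 500.0, "t2": 600.0, "t3": 700.0, "t4": 900.0, "t5": 800.0},
    )
    base.update(over)
    return bh.ScenarioParams(**base)


class TestSampleConfig:
    def test_default_mirrors_study_design(self):
        cfg = bh.SampleConfig()
        assert cfg.total_haploids == 798
        assert cfg.n_snps == 1435
        assert len(cfg.diploid_samples()) == 399
        assert cfg.popmap().group_sizes() == {
            "ALE": 45, "AKBC": 70, "COAST": 30, "NORTH": 62, "SOUTH": 42, "UK": 150,
        }

    def test_odd_haploid_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            bh.SampleConfig(haploids={"UK": 3})

    def test_unknown_deme_rejected(self):
        with pytest.raises(ValueError):
            bh.SampleConfig(haploids={"ATLANTIS": 4})


class TestSimulateTree:
    def test_tree_invariants(self, tiny_config, two_wave_truth, informative_params):
        rng = np.random.default_rng(0)
        tree = bh.simulate_tree(two_wave_truth, informative_params, tiny_config, rng)
        tree.validate()
        assert tree.n_tips == tiny_config.total_haploids
        assert tree.tmrca > 0
        assert tree.total_branch_length > tree.tmrca

    def test_pairwise_tmrca_matches_closed_form(self):
        # E[T2] = 2 Ne generations for two lineages in one deme
        ne = 500.0
        cfg = bh.SampleConfig(haploids={"UK": 2}, n_snps=1)
        rng = np.random.default_rng(1)
        times = [
            bh.simulate_tree(None, None, cfg, rng, panmictic_ne=ne).tmrca
            for _ in range(5000)
        ]
        assert np.mean(times) == pytest.approx(2 * ne, rel=0.05)

    def test_null_wave_leaves_tmrca_distribution_unchanged(self, tiny_config):
        # a wave with the minimum proportion 0.001 is statistically inert
        single = bh.Scenario("A2", "AKBC")
        waved = bh.Scenario("B3", "AKBC", ("NORTH",))
        p_single = _single_pop_params()
        p_waved = _single_pop_params(wave_times=(50.0,), wave_props=(0.001,))
        rng = np.random.default_rng(2)
        t_single = [
            bh.simulate_tree(single, p_single, tiny_config, rng).tmrca
            for _ in range(2000)
        ]
        t_waved = [
            bh.simulate_tree(waved, p_waved, tiny_config, rng).tmrca
            for _ in range(2000)
        ]
        assert stats.ks_2samp(t_single, t_waved).pvalue > 0.01

    def test_full_replacement_wave_equals_rebased_founding(self, tiny_config):
        # p_w ~ 1 at t0b moves every introduced lineage to the wave origin,
        # which is the same process as founding from that origin at t0b
        waved = bh.Scenario("B7", "NORTH", ("AKBC",))
        p_waved = _single_pop_params(wave_times=(50.0,), wave_props=(0.999,))
        direct = bh.Scenario("A2", "AKBC")
        p_direct = _single_pop_params(t0a=50.0)
        rng = np.random.default_rng(3)
        t_w = [
            bh.simulate_tree(waved, p_waved, tiny_config, rng).tmrca
            for _ in range(2000)
        ]
        t_d = [
            bh.simulate_tree(direct, p_direct, tiny_config, rng).tmrca
            for _ in range(2000)
        ]
        assert stats.ks_2samp(t_w, t_d).pvalue > 0.01


class TestDropMutation:
    def test_two_tip_symmetry(self):
        cfg = bh.SampleConfig(haploids={"UK": 2}, n_snps=1)
        rng = np.random.default_rng(4)
        derived_first = 0
        for _ in range(2000):
            tree = bh.simulate_tree(None, None, cfg, rng, panmictic_ne=100.0)
            col = bh.drop_mutation(tree, rng)
            assert col.sum() == 1  # exactly one derived tip on a 2-tip tree
            derived_first += int(col[0])
        assert stats.binomtest(derived_first, 2000, 0.5).pvalue > 0.001

    def test_always_polymorphic(self):
        cfg = bh.SampleConfig(haploids={"UK": 10}, n_snps=1)
        rng = np.random.default_rng(5)
        for _ in range(300):
            tree = bh.simulate_tree(None, None, cfg, rng, panmictic_ne=300.0)
            col = bh.drop_mutation(tree, rng)
            assert 0 < col.sum() < tree.n_tips

    def test_degenerate_tree_rejected(self):
        parent = np.array([2, 2, -1])
        node_time = np.zeros(3)
        tree = CoalescentTree(parent, node_time, np.zeros(2, dtype=np.int8))
        with pytest.raises(ValueError, match="zero total branch length"):
            bh.drop_mutation(tree, np.random.default_rng(0))

    def test_neutral_sfs_follows_one_over_i(self):
        # derived-allele count i has expected frequency proportional to 1/i
        n = 20
        hap = bh.panmictic_snps(n, ne=1000.0, n_snps=20000, seed=99)
        counts = hap.sum(axis=1)
        assert counts.min() >= 1 and counts.max() <= n - 1
        observed = np.bincount(counts, minlength=n)[1:n]
        weights = 1.0 / np.arange(1, n)
        expected = 20000 * weights / weights.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=n - 2)
        assert p > 0.01


class TestSimulateDataset:
    def test_no_missing_when_rate_zero(self, tiny_config, two_wave_truth, informative_params):
        rng = np.random.default_rng(6)
        gm = bh.simulate_dataset(
            two_wave_truth, informative_params, tiny_config, 0.0, rng
        )
        assert (gm.calls != bh.MISSING).all()
        assert gm.n_sites == tiny_config.n_snps

    def test_missing_rate_concentrates(self, two_wave_truth, informative_params):
        cfg = bh.SampleConfig(n_snps=1435)  # study scale: 1435 x 399 calls
        rng = np.random.default_rng(7)
        gm = bh.simulate_dataset(two_wave_truth, informative_params, cfg, 0.2, rng)
        assert gm.missing_rate() == pytest.approx(0.2, abs=0.01)

    def test_per_deme_missing_profile(self, tiny_config, two_wave_truth, informative_params):
        rng = np.random.default_rng(8)
        gm = bh.simulate_dataset(
            two_wave_truth,
            informative_params,
            tiny_config,
            {"UK": 0.5},
            rng,
        )
        pm = tiny_config.popmap()
        uk_rows = [gm.samples.index(s) for s in pm.samples_of_group("UK")]
        other = [i for i in range(gm.n_samples) if i not in uk_rows]
        assert (gm.calls[uk_rows] == bh.MISSING).mean() == pytest.approx(0.5, abs=0.05)
        assert (gm.calls[other] != bh.MISSING).all()

    def test_deep_split_fst_approaches_one(self):
        # two demes separated for >> 4Ne generations fix alternative alleles
        cfg = bh.SampleConfig(haploids={"ALE": 30, "AKBC": 30}, n_snps=5000)
        params = _single_pop_params(
            ne=200.0,
            splits={"t1": 50000.0, "t2": 60000.0, "t3": 70000.0,
                    "t4": 60000.0, "t5": 50000.0},
        )
        sc = bh.Scenario("A2", "AKBC")
        rng = np.random.default_rng(9)
        gm = bh.simulate_dataset(sc, params, cfg, 0.0, rng)
        fst = bh.fst_pairwise(gm, cfg.popmap(), "ALE", "AKBC")
        assert fst > 0.95

    def test_hwe_pairing_preserves_allele_counts(self, tiny_config):
        rng = np.random.default_rng(10)
        hap = (rng.random((50, tiny_config.total_haploids)) < 0.3).astype(np.uint8)
        calls = pair_haploids(hap, tiny_config, rng)
        assert calls.shape == (tiny_config.total_haploids // 2, 50)
        np.testing.assert_array_equal(calls.sum(axis=0), hap.sum(axis=1))


class TestReferenceTable:
    def test_smoke_no_nan_without_missingness(self, tiny_config, two_wave_truth):
        tab = bh.reference_table(
            two_wave_truth, bh.PriorSpec(), 10, tiny_config, seed=1
        )
        assert len(tab) == 10
        stat_cols = tab.attrs["stat_names"]
        assert not tab[stat_cols].isna().any().any()
        assert (tab["model"] == "TRUTH").all()

    def test_identical_seed_identical_table(self, tiny_config, two_wave_truth):
        t1 = bh.reference_table(two_wave_truth, bh.PriorSpec(), 5, tiny_config, seed=3)
        t2 = bh.reference_table(two_wave_truth, bh.PriorSpec(), 5, tiny_config, seed=3)
        assert t1.equals(t2)

    def test_divergence_priors_separate_fst(self, tiny_config):
        from bridgehead.scenarios import Dist

        sc = bh.Scenario("A2", "AKBC")
        shallow = bh.PriorSpec(split=Dist("uniform", 500.0, 1000.0))
        deep = bh.PriorSpec(split=Dist("uniform", 15000.0, 20000.0))
        t_lo = bh.reference_table(sc, shallow, 100, tiny_config, seed=5)
        t_hi = bh.reference_table(sc, deep, 100, tiny_config, seed=5)
        fst_cols = [c for c in t_lo.columns if c.startswith("pair:") and c.endswith(":fst")]
        lo = t_lo[fst_cols].mean(axis=1)
        hi = t_hi[fst_cols].mean(axis=1)
        assert stats.ttest_ind(hi, lo, equal_var=False).pvalue < 1e-6
        assert hi.mean() > lo.mean()


class TestEventTable:
    def test_events_sorted_and_complete(self, two_wave_truth, informative_params):
        times, kinds, srcs, dsts, probs = build_events(
            two_wave_truth, informative_params
        )
        assert np.all(np.diff(times) >= 0)
        assert len(times) == 1 + 1 + 5  # wave + founding + five splits
        assert (kinds == 1).sum() == 1  # one probabilistic pulse

    def test_haploid_relabelling_within_deme_preserves_deme_counts(
        self, tiny_config
    ):
        # per-deme allele counts (hence every summary statistic) are
        # invariant to relabelling haploids within a deme
        rng = np.random.default_rng(11)
        hap = (rng.random((40, tiny_config.total_haploids)) < 0.4).astype(np.uint8)
        hap_perm = hap.copy()
        start = 0
        for g in tiny_config.groups:
            h = tiny_config.haploids[g]
            perm = start + rng.permutation(h)
            hap_perm[:, start : start + h] = hap[:, perm]
            start += h
        c1 = pair_haploids(hap, tiny_config, np.random.default_rng(0))
        c2 = pair_haploids(hap_perm, tiny_config, np.random.default_rng(0))
        start = 0
        for g in tiny_config.groups:
            n_dip = tiny_config.haploids[g] // 2
            block1 = c1[start : start + n_dip]
            block2 = c2[start : start + n_dip]
            np.testing.assert_array_equal(block1.sum(axis=0), block2.sum(axis=0))
            start += n_dip


class TestMsprimeCrossCheck:
    def test_split_model_tmrca_distribution_matches_msprime(self):
        msprime = pytest.importorskip("msprime")
        ne, t_split = 800.0, 1500.0
        cfg = bh.SampleConfig(haploids={"ALE": 6, "AKBC": 6}, n_snps=1)
        params = _single_pop_params(
            ne=ne,
            splits={"t1": t_split, "t2": 90000.0, "t3": 95000.0,
                    "t4": 93000.0, "t5": 91000.0},
        )
        sc = bh.Scenario("A2", "AKBC")
        rng = np.random.default_rng(12)
        ours = [
            bh.simulate_tree(sc, params, cfg, rng).tmrca for _ in range(800)
        ]
        dem = msprime.Demography()
        dem.add_population(name="ALE", initial_size=ne)
        dem.add_population(name="AKBC", initial_size=ne)
        dem.add_population(name="ANC", initial_size=ne)
        dem.add_population_split(time=t_split, derived=["ALE", "AKBC"], ancestral="ANC")
        theirs = []
        for ts in msprime.sim_ancestry(
            samples={"ALE": 3, "AKBC": 3},  # diploid samples = 6 haploids
            demography=dem,
            num_replicates=800,
            random_seed=1234,
        ):
            theirs.append(ts.max_root_time)
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01
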