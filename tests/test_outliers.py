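import warnings

import numpy as np
import pytest
from scipy.stats import binom, kstest

from parashore.datamodel import GenotypeMatrix
from parashore.outliers import (
    consensus_loci,
    fdist_pvalues,
    fdist_simulate_null,
    fdist_target_fst,
    fmodel_scan,
    island_migration_rate,
    pca_scan,
    scan_site,
    sgof,
)
from parashore.synthetic import SimConfig, simulate_dataset


def _gm(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n)],
                          [(j + 1, 0) for j in range(L)])


def sgof_bruteforce(p, gamma=0.05, alpha=0.05):
    """Independent direct-binomial-tail SGoF implementation."""
    p = np.asarray(p)
    n = len(p)
    if n == 0:
        return 0
    big_r = int((p <= gamma).sum())
    s = 0
    for r in range(big_r, 0, -1):
        tail = sum(binom.pmf(k, n, gamma) for k in range(r, n + 1))
        if tail <= alpha:
            s = big_r - r + 1
        else:
            break
    return s


class TestSgof:
    def test_all_ones_no_rejections(self):
        s, flags = sgof(np.ones(100))
        assert s == 0 and not flags.any()

    def test_all_zero_matches_binomial_recursion(self):
        s, flags = sgof(np.zeros(100))
        assert s == sgof_bruteforce(np.zeros(100))
        assert flags.sum() == s

    def test_empty_input(self):
        s, flags = sgof([])
        assert s == 0

    def test_flags_are_smallest_pvalues(self):
        rng = np.random.default_rng(0)
        p = rng.random(60) ** 3
        s, flags = sgof(p)
        if s:
            assert p[flags].max() <= p[~flags].min()

    def test_uniform_null_rarely_rejects(self):
        rng = np.random.default_rng(1)
        counts = [sgof(rng.random(1000))[0] for _ in range(30)]
        assert np.mean(counts) < 20

    def test_domain_check(self):
        with pytest.raises(ValueError):
            sgof([0.5, 1.2])


class TestFdistNull:
    def test_migration_rate_solves_expectation(self):
        assert island_migration_rate(0.5, 100) == pytest.approx(
            1.0 * (99 / 100) ** 2
        )
        with pytest.raises(ValueError):
            island_migration_rate(0.95, 100)

    def test_null_mean_matches_target(self):
        from scipy.stats import trim_mean

        null = fdist_simulate_null(0.25, n_sims=600, sample_sizes=(20, 20),
                                   seed=3)
        assert trim_mean(null.theta, 0.05) == pytest.approx(0.25, abs=0.03)

    def test_low_target_panmixia_limit(self):
        null = fdist_simulate_null(0.01, n_sims=300, sample_sizes=(15, 15),
                                   seed=4, calibrate=False)
        assert abs(np.median(null.theta)) < 0.05

    def test_deterministic_given_seed(self):
        a = fdist_simulate_null(0.3, n_sims=150, sample_sizes=(10, 10), seed=5,
                                calibrate=False)
        b = fdist_simulate_null(0.3, n_sims=150, sample_sizes=(10, 10), seed=5,
                                calibrate=False)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.he, b.he)

    def test_gillespie_agrees_with_msprime_engine(self):
        # same island model, independent simulators: theta distributions
        # should be statistically indistinguishable (single-mutation mode)
        kw = dict(n_demes=20, n_sims=250, sample_sizes=(12, 12),
                  calibrate=False, mutation="single")
        ours = fdist_simulate_null(0.3, seed=6, engine="gillespie", **kw)
        ref = fdist_simulate_null(0.3, seed=7, engine="msprime", **kw)
        assert kstest(ours.theta, ref.theta).pvalue > 0.01

    def test_extreme_locus_minimal_p(self):
        null = fdist_simulate_null(0.1, n_sims=400, sample_sizes=(15, 15),
                                   seed=8, calibrate=False)
        import pandas as pd

        obs = pd.DataFrame({"he": [0.4], "theta": [0.999]})
        pv = fdist_pvalues(obs, null)
        k = null.neighborhood
        assert pv["p_upper"].iloc[0] == pytest.approx(1 / (k + 1))

    def test_monomorphic_locus_gets_no_pvalue(self):
        null = fdist_simulate_null(0.1, n_sims=300, sample_sizes=(15, 15),
                                   seed=9, calibrate=False)
        import pandas as pd

        obs = pd.DataFrame({"he": [0.3, np.nan], "theta": [0.1, np.nan]})
        pv = fdist_pvalues(obs, null)
        assert not np.isnan(pv["p_upper"].iloc[0])
        assert np.isnan(pv["p_upper"].iloc[1])

    def test_target_estimator_trims_outliers(self):
        # a <=5% contamination fraction is absorbed by the two-sided trim;
        # larger fractions are handled by the scan's re-estimation round
        theta = np.concatenate([np.full(95, 0.1), np.full(5, 0.9)])
        assert fdist_target_fst(theta) == pytest.approx(0.1, abs=0.02)


class TestPcaScan:
    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(10)
        L = 2000
        p0 = rng.uniform(0.1, 0.9, L)
        sel = rng.choice(L, 50, replace=False)
        p1, p2 = p0.copy(), p0.copy()
        p1[sel] = 0.10
        p2[sel] = 0.90
        d = np.vstack([rng.binomial(2, p1, (30, L)),
                       rng.binomial(2, p2, (30, L))])
        res = pca_scan(_gm(d), K=1, fdr=0.05)
        names = np.array([f"rad{j + 1}_0" for j in range(L)])
        flagged = set(res.index[res["flag"]])
        assert len(flagged & set(names[sel])) >= 45
        assert len(flagged - set(names[sel])) <= 10

    def test_homogeneous_sample_flags_nothing_much(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 500), (50, 500))
        res = pca_scan(_gm(d), K=1)
        assert res["flag"].sum() <= 5

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 200), (30, 200))
        r1 = pca_scan(_gm(d))
        r2 = pca_scan(_gm(d))
        assert r1["stat"].equals(r2["stat"])


class TestFmodel:
    def _site(self, seed, n_div=0, delta=0.9, L=200):
        cfg = SimConfig(
            seed=seed, n_loci=L, n_per_level=30, sites=("S1",),
            refugium_of={"S1": "south"},
            n_divergent_shared_all=0, n_divergent_shared_southern=0,
            n_divergent_private=n_div, delta=delta, n_balancing=0,
            missing_rate=0.0,
        )
        return simulate_dataset(cfg)

    _kw = dict(pilot_runs=4, pilot_len=50, burn_in=500, thin=2, n_samples=300)

    def test_fixed_difference_high_inclusion(self):
        gm, h, truth = self._site(seed=61, n_div=4, delta=1.0)
        # force hard fixed differences at the planted loci
        div = np.flatnonzero(truth.locus_class == "divergent")
        ia = h.indices_for(gm, site="S1", tidal_level="upper")
        ib = h.indices_for(gm, site="S1", tidal_level="lower")
        d = gm.dosages.copy()
        d[np.ix_(ia, div)] = 2
        d[np.ix_(ib, div)] = 0
        gm = GenotypeMatrix(d, gm.sample_ids, gm.locus_ids, gm.alleles)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = fmodel_scan(gm, h, "S1", seed=1, **self._kw)
        assert (fm.inclusion.iloc[div] > 0.95).all()

    def test_null_site_flags_nothing(self):
        gm, h, _ = self._site(seed=62)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = fmodel_scan(gm, h, "S1", seed=2, **self._kw)
        assert fm.flags.sum() == 0

    def test_deterministic_given_seed(self):
        gm, h, _ = self._site(seed=63, L=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fmodel_scan(gm, h, "S1", seed=3, **self._kw)
            b = fmodel_scan(gm, h, "S1", seed=3, **self._kw)
        assert a.inclusion.equals(b.inclusion)

    def test_qvalues_nondecreasing_in_rank(self):
        gm, h, _ = self._site(seed=64, n_div=3, L=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = fmodel_scan(gm, h, "S1", seed=4, **self._kw)
        order = np.argsort(-fm.inclusion.to_numpy(), kind="stable")
        q_ranked = fm.q.to_numpy()[order]
        assert (np.diff(q_ranked) >= -1e-12).all()


class TestConsensus:
    def test_two_of_three_rule(self):
        sets = {"m1": {"A", "B"}, "m2": {"B", "C"}, "m3": {"C"}}
        assert consensus_loci(sets) == {"B", "C"}

    def test_identical_sets(self):
        sets = {"m1": {"A", "B"}, "m2": {"A", "B"}}
        assert consensus_loci(sets) == {"A", "B"}

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            consensus_loci({"m1": {"A"}})


class TestScanSite:
    def test_recovers_planted_divergence(self):
        cfg = SimConfig(
            seed=71, n_loci=500, n_per_level=25, sites=("S1",),
            refugium_of={"S1": "south"},
            n_divergent_shared_all=0, n_divergent_shared_southern=0,
            n_divergent_private=20, delta=0.9, n_balancing=0,
            missing_rate=0.05,
        )
        gm, h, truth = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scan_site(
                gm, h, "S1", n_sims=800, seed=5,
                recalibrate=False,
                fmodel_kwargs=dict(pilot_runs=4, pilot_len=50, burn_in=400,
                                   thin=2, n_samples=200),
            )
        names = np.array(gm.locus_names)
        div = truth.divergent_loci_for("S1", names)
        hits = res.outliers.consensus & div
        # consensus recovers the majority of strongly divergent loci with
        # a false-positive rate no worse than the single methods
        assert len(hits) >= 0.5 * len(div & set(res.stats.index))
        fp_consensus = len(res.outliers.consensus - div)
        for m, s in res.outliers.method_sets.items():
            assert fp_consensus <= max(len(s - div), 1)
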