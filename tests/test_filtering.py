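from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parashore.datamodel import GenotypeMatrix, SampleHierarchy
from parashore.filtering import (
    filter_loci,
    first_snp_per_rad_locus,
    hwe_exact_test,
    hwe_flag,
    ld_flag,
)


def _gm(dosages, rad_ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    ids = rad_ids or [(j + 1, 0) for j in range(L)]
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n)], ids)


class TestThresholds:
    def test_call_rate_boundary(self):
        # 100 individuals: 69 genotyped -> removed; 70 genotyped -> retained
        col69 = [1] * 69 + [-1] * 31
        col70 = [1] * 70 + [-1] * 30
        gm = _gm(np.array([col69, col70]).T)
        out, report = filter_loci(gm)
        assert report.loci.loc["rad1_0", "reason"] == "call_rate"
        assert report.loci.loc["rad2_0", "retained"]
        assert out.n_loci == 1

    def test_maf_exactly_one_percent_removed(self):
        # 100 individuals, minor allele count 2 -> MAF exactly 0.01 (> rule strict)
        col = [1] * 2 + [0] * 98
        common = [1] * 50 + [0] * 50
        gm = _gm(np.array([col, common]).T)
        out, report = filter_loci(gm)
        assert report.loci.loc["rad1_0", "reason"] == "maf"
        assert out.locus_names == ["rad2_0"]

    def test_planted_failures_counted(self):
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.5, size=(50, 90))
        bad_cr = np.full((50, 5), -1)
        bad_cr[:10] = 1
        bad_maf = np.zeros((50, 5), int)
        gm = _gm(np.hstack([good, bad_cr, bad_maf]))
        out, report = filter_loci(gm)
        assert out.n_loci == 90
        assert (~report.loci["retained"]).sum() == 10

    def test_threshold_domain_checked(self, tiny_gm):
        gm, _ = tiny_gm
        with pytest.raises(ValueError):
            filter_loci(gm, call_rate_min=1.5)


class TestFirstSnp:
    def test_minimal_offset_kept(self):
        gm = _gm(np.zeros((2, 5), int) + 1,
                 rad_ids=[(1, 40), (1, 12), (2, 3), (3, 7), (3, 7 + 1)])
        out = first_snp_per_rad_locus(gm)
        assert out.locus_ids == [(1, 12), (2, 3), (3, 7)]

    def test_singletons_identity(self, tiny_gm):
        gm, _ = tiny_gm
        out = first_snp_per_rad_locus(gm)
        assert out.locus_ids == gm.locus_ids


class TestHweExact:
    @given(
        st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_for_small_margins(self, naa, nab, nbb):
        if naa + nab + nbb == 0 or naa + nab + nbb > 20:
            return
        p = hwe_exact_test(naa, nab, nbb)
        n = naa + nab + nbb
        n_a, n_b = 2 * naa + nab, 2 * nbb + nab
        rare = min(n_a, n_b)
        if rare == 0:
            assert p == 1.0
            return
        weights = {}
        for het in range(rare % 2, rare + 1, 2):
            homr = (rare - het) // 2
            homc = n - het - homr
            weights[het] = (
                comb(n, het) * comb(n - het, homr) * 2**het
            )
        total = sum(weights.values())
        obs = weights[nab]
        expected = sum(v for v in weights.values() if v <= obs) / total
        assert p == pytest.approx(expected, rel=1e-9)

    def test_known_cases(self):
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)
        assert hwe_exact_test(5, 0, 0) == 1.0  # monomorphic

    def test_extreme_heterozygote_excess_near_minimal_p(self):
        # all-het is the most extreme heterozygote-excess configuration for
        # its allele margin (two-sided p can be beaten only by extreme
        # homozygote excess, which is more probable under the margin)
        n = 40
        p_all_het = hwe_exact_test(0, n, 0)
        assert p_all_het < 1e-9
        excess_side = [hwe_exact_test((n - h) // 2, h, (n - h) // 2)
                       for h in range(n // 2, n + 1, 2)]
        assert p_all_het == min(excess_side)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestHweFlag:
    def _dataset(self, cols, n=60):
        dosages = np.array(cols).T
        gm = _gm(dosages)
        recs = [(f"s{i}", "S1", "T1", "upper" if i < n // 2 else "lower")
                for i in range(n)]
        return gm, SampleHierarchy.from_records(recs)

    def test_hwe_data_rarely_flagged(self):
        rng = np.random.default_rng(1)
        cols = [rng.binomial(2, rng.uniform(0.1, 0.9), 60) for _ in range(500)]
        gm, h = self._dataset(cols)
        report = hwe_flag(gm, h)
        frac = report.hwe_flagged.any(axis=0).mean()
        assert frac < 0.05

    def test_alpha_zero_flags_nothing(self):
        rng = np.random.default_rng(2)
        cols = [rng.binomial(2, 0.5, 60) for _ in range(50)]
        gm, h = self._dataset(cols)
        report = hwe_flag(gm, h, alpha=0.0)
        assert not report.hwe_flagged.to_numpy().any()

    def test_planted_het_excess_all_flagged(self):
        rng = np.random.default_rng(3)
        cols = [rng.binomial(2, 0.5, 60) for _ in range(200)]
        cols += [np.ones(60, int) for _ in range(10)]  # all-het loci
        gm, h = self._dataset(cols)
        report = hwe_flag(gm, h)
        planted = [f"rad{j + 1}_0" for j in range(200, 210)]
        assert report.hwe_flagged[planted].all(axis=None)

    def test_flagged_loci_are_not_removed(self):
        rng = np.random.default_rng(4)
        cols = [rng.binomial(2, 0.5, 60) for _ in range(20)]
        gm, h = self._dataset(cols)
        report = hwe_flag(gm, h)
        assert len(report.hwe.columns) == gm.n_loci


class TestLdFlag:
    def _three_site(self, n_per_site=40, L=30, seed=5, dup=True):
        rng = np.random.default_rng(seed)
        cols = rng.binomial(2, rng.uniform(0.2, 0.8, L),
                            (3 * n_per_site, L)).astype(np.int8)
        if dup:
            cols[:, 1] = cols[:, 0]  # perfect duplicate pair
        gm = _gm(cols)
        recs = []
        for i in range(3 * n_per_site):
            site = f"S{i // n_per_site + 1}"
            recs.append((f"s{i}", site, "T1", "upper"))
        return gm, SampleHierarchy.from_records(recs)

    def test_duplicate_columns_flagged_in_all_sites(self):
        gm, h = self._three_site()
        report = ld_flag(gm, h)
        assert report.ld_linked["rad1_0"] and report.ld_linked["rad2_0"]
        assert {"rad1_0", "rad2_0"} == set(
            report.ld_pairs.iloc[0][["locus_a", "locus_b"]]
        )

    def test_independent_loci_rarely_flagged(self):
        gm, h = self._three_site(dup=False, L=60, n_per_site=60)
        report = ld_flag(gm, h)
        assert report.ld_linked.mean() < 0.1

    def test_all_sites_rule(self):
        # pair correlated in two sites, independent in the third -> not flagged
        rng = np.random.default_rng(6)
        n = 40
        base = rng.binomial(2, 0.5, 3 * n).astype(np.int8)
        partner = base.copy()
        partner[2 * n:] = rng.binomial(2, 0.5, n)  # decouple in site 3
        filler = rng.binomial(2, 0.5, (3 * n, 3)).astype(np.int8)
        gm = _gm(np.column_stack([base, partner, filler]))
        recs = [(f"s{i}", f"S{i // n + 1}", "T1", "upper")
                for i in range(3 * n)]
        h = SampleHierarchy.from_records(recs)
        report = ld_flag(gm, h)
        assert not report.ld_linked["rad1_0"]
        assert not report.ld_linked["rad2_0"]
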