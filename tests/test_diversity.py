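"""Window diversity statistics, callable masks and the sex-difference scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parevo import diversity as dv
from parevo.io import GenomicIntervals


def make_sites(gt, pos=None, sex=None, mut_class=None, anc=None):
    gt = np.asarray(gt, dtype=np.int8)
    m, ns = gt.shape
    pos = np.arange(m) if pos is None else np.asarray(pos)
    sex = np.array(["F", "M"] * (ns // 2) + ["F"] * (ns % 2)) if sex is None \
        else np.asarray(sex)
    ref = np.full(m, "T")
    alt = np.full(m, "C")
    return dv.SiteTable(pos, ref, alt, ref.copy() if anc is None else anc,
                        gt, [f"s{i}" for i in range(ns)], sex,
                        mut_class=mut_class)


def full_mask(length, window=10_000):
    return dv.CallableMask(GenomicIntervals("PAR1", [0], [length]),
                           region_length=length, window=window)


class TestCallableMask:
    def test_depth_below_lower_bound(self):
        mask = dv.callable_mask_from_depth(np.array([1.0, 2.9, 3.0]), n=2,
                                           mean_cov=10)
        assert list(mask.contains([0, 1, 2])) == [False, False, True]

    def test_upper_bound_inclusive(self):
        # 2 * n * cov = 40 exactly is still callable, 41 is not
        mask = dv.callable_mask_from_depth(np.array([40.0, 41.0]), n=2,
                                           mean_cov=10)
        assert list(mask.contains([0, 1])) == [True, False]

    def test_uniform_mean_depth_all_callable(self):
        depth = np.full(1000, 30.0)
        mask = dv.callable_mask_from_depth(depth, n=2, mean_cov=15)
        assert mask.n_callable == 1000

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            dv.callable_mask_from_depth(np.array([-1.0]), n=2, mean_cov=10)

    def test_window_counts_cap(self):
        depth = np.full(25_000, 10.0)
        mask = dv.callable_mask_from_depth(depth, n=2, mean_cov=10)
        assert list(mask.window_callable()) == [10_000, 10_000, 5_000]


class TestPi:
    def test_monomorphic_window_zero(self):
        sites = make_sites(np.zeros((5, 4)))
        mask = full_mask(10_000)
        assert dv.nucleotide_diversity_pi(sites, mask, (0, 10_000)) == 0.0

    def test_two_chromosome_example(self):
        # one heterozygous individual: 1 difference over 100 callable sites
        sites = make_sites([[1]])
        mask = dv.CallableMask(GenomicIntervals("PAR1", [0], [100]),
                               region_length=100, window=100)
        pi = dv.nucleotide_diversity_pi(sites, mask, (0, 100), min_callable=50)
        assert pi == pytest.approx(0.01)

    def test_matches_brute_force_pairwise_differences(self):
        """Site-summed 2p(1-p)n/(n-1) equals the mean pairwise difference
        count over all chromosome pairs (complete data)."""
        rng = np.random.default_rng(5)
        n_ind = 6
        hap = rng.integers(0, 2, size=(40, 2 * n_ind))
        gt = hap.reshape(40, n_ind, 2).sum(axis=2)
        sites = make_sites(gt)
        mask = full_mask(10_000)
        pi = dv.nucleotide_diversity_pi(sites, mask, (0, 10_000))
        # brute force: average over all chromosome pairs
        diffs = sum((hap[:, i] != hap[:, j]).sum()
                    for i in range(12) for j in range(i + 1, 12))
        expected = diffs / (12 * 11 / 2) / 10_000
        assert pi == pytest.approx(expected, rel=1e-12)

    def test_failing_window_flagged_nan(self):
        sites = make_sites([[1]])
        mask = dv.CallableMask(GenomicIntervals("PAR1", [0], [100]),
                               region_length=10_000)
        assert np.isnan(dv.nucleotide_diversity_pi(sites, mask, (0, 10_000)))


class TestWattersonTheta:
    def test_two_chromosomes_identity(self):
        assert dv.watterson_theta(7, 2, 100) == pytest.approx(0.07)

    def test_harmonic_example(self):
        # S=25, n=11 chromosomes, a_10 = 2.928968...
        theta = dv.watterson_theta(25, 11, 10_000)
        assert theta == pytest.approx(25 / (2.9289682539682538 * 10_000))
        assert theta == pytest.approx(8.5355e-4, rel=1e-4)

    def test_no_segregating_sites(self):
        assert dv.watterson_theta(0, 10, 1000) == 0.0


def brute_force_tajima(S, n, pi_total):
    """Independent transcription of the published constants."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
    return (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_zero_when_pi_equals_theta(self):
        a9 = sum(1 / i for i in range(1, 10))
        assert dv.tajimas_d(16, 10, 16 / a9) == pytest.approx(0.0)

    def test_against_independent_transcription(self):
        rng = np.random.default_rng(2)
        gt = rng.integers(0, 2, size=(16, 10, 2)).sum(axis=2)
        sites = make_sites(gt)
        ac, an = sites.alt_counts()
        p = ac / an
        pi_total = float(np.sum(2 * p * (1 - p) * an / (an - 1)))
        assert dv.tajimas_d(16, 20, pi_total) == pytest.approx(
            brute_force_tajima(16, 20, pi_total), rel=1e-12)

    def test_undefined_without_segregating_sites(self):
        with pytest.raises(ValueError):
            dv.tajimas_d(0, 10, 0.0)


class TestHeterozygosity:
    def test_counts_het_sites_per_callable(self):
        mask = full_mask(10_000)
        gt = np.array([1] * 8 + [0, 2, 2])
        pos = np.arange(11) * 100
        assert dv.heterozygosity(gt, pos, mask, (0, 10_000)) == pytest.approx(8e-4)
        assert dv.heterozygosity(np.array([0, 2]), np.array([1, 2]), mask,
                                 (0, 10_000)) == 0.0


class TestWindowStatistics:
    def _sim_table(self, theta=0.002, L=200_000, n_ind=10, seed=9):
        """Independent-site neutral polymorphism at per-site theta."""
        rng = np.random.default_rng(seed)
        n = 2 * n_ind
        a_n = sum(1 / i for i in range(1, n))
        i_cat = np.arange(1, n)
        lam = theta * L / i_cat
        counts = rng.poisson(lam)
        m = counts.sum()
        pos = np.sort(rng.choice(L, size=m, replace=False))
        derived = np.repeat(i_cat, counts)
        rng.shuffle(derived)
        gt = np.zeros((m, n_ind), dtype=np.int8)
        for j, d in enumerate(derived):
            chroms = rng.permutation(n) < d
            gt[j] = chroms.reshape(n_ind, 2).sum(axis=1)
        return make_sites(gt, pos=pos), L

    def test_neutral_expectations(self):
        """E[pi] ~ E[theta_W] ~ configured theta; mean Tajima's D ~ 0."""
        sites, L = self._sim_table()
        mask = full_mask(L)
        win = dv.window_statistics(sites, mask)
        ok = win[win["pass_filter"]]
        assert ok["pi"].mean() == pytest.approx(0.002, rel=0.1)
        assert ok["theta_w"].mean() == pytest.approx(0.002, rel=0.1)
        assert abs(ok["tajimas_d"].mean()) < 0.25

    def test_invariant_to_sample_order(self):
        sites, L = self._sim_table(L=50_000)
        mask = full_mask(L)
        perm = np.random.default_rng(0).permutation(sites.n_samples)
        shuffled = dv.SiteTable(sites.pos, sites.ref, sites.alt, sites.anc,
                                sites.gt[:, perm],
                                [sites.samples[i] for i in perm],
                                sites.sex[perm])
        pd.testing.assert_frame_equal(dv.window_statistics(sites, mask),
                                      dv.window_statistics(shuffled, mask))

    def test_complete_filter_never_increases_s(self):
        sites, L = self._sim_table(L=50_000)
        gt = sites.gt.copy()
        gt[::3, 0] = dv.MISSING
        with_missing = dv.SiteTable(sites.pos, sites.ref, sites.alt,
                                    sites.anc, gt, sites.samples, sites.sex)
        mask = full_mask(L)
        s_all = dv.window_statistics(sites, mask)["S"].sum()
        s_complete = dv.window_statistics(with_missing, mask)["S"].sum()
        assert s_complete <= s_all


class TestDiversitySpectrum:
    def test_single_class(self):
        sites = make_sites([[1], [1]], mut_class=np.array(["CpG>TpG"] * 2))
        s = dv.diversity_spectrum(sites)
        assert s["CpG>TpG"] == 1.0 and s.sum() == 1.0

    def test_uniform_classes(self):
        from parevo.alignment import CLASSES
        gt = np.ones((7, 1), dtype=np.int8)
        sites = make_sites(gt, mut_class=np.array(CLASSES))
        assert np.allclose(dv.diversity_spectrum(sites), 1 / 7)

    def test_matches_generator_theta_shares(self, small_sites):
        sites, _ = small_sites
        from parevo.synthetic import SimulationConfig
        cfg = SimulationConfig(seed=0)
        s = dv.diversity_spectrum(sites)
        # CpG transitions are enriched relative to e.g. T>G, as configured
        assert s["CpG>TpG"] > 2 * s["T>G"]
        theta = cfg.theta_class
        share = {k: v / sum(theta.values()) for k, v in theta.items()}
        for cls in ("C>T", "CpG>TpG", "T>A"):
            assert s[cls] == pytest.approx(share[cls], rel=0.25)


class TestSexScan:
    def test_identical_counts_give_p_one(self):
        gt = np.tile([1, 1, 1, 1], (3, 1)).astype(np.int8)
        sites = make_sites(gt, sex=np.array(["F", "F", "M", "M"]))
        out = dv.sex_diff_scan(sites)
        assert (out["p"] == 1.0).all()
        assert not out["discovery"].any()

    def test_fixed_difference_matches_hypergeometric_oracle(self):
        # females 20/0, males 0/20 alleles
        gt = np.array([[2] * 10 + [0] * 10], dtype=np.int8)
        sites = make_sites(gt, sex=np.array(["F"] * 10 + ["M"] * 10))
        out = dv.sex_diff_scan(sites)
        # exhaustive hypergeometric enumeration of tables at least as extreme
        p_oracle = sum(stats.hypergeom.pmf(k, 40, 20, 20)
                       for k in range(41)
                       if stats.hypergeom.pmf(k, 40, 20, 20)
                       <= stats.hypergeom.pmf(20, 40, 20, 20) * (1 + 1e-9))
        assert out["p"].iloc[0] == pytest.approx(p_oracle, rel=1e-6)
        assert out["discovery"].iloc[0]

    def test_single_sex_rejected(self):
        sites = make_sites([[1, 1]], sex=np.array(["F", "F"]))
        with pytest.raises(ValueError):
            dv.sex_diff_scan(sites)

    def test_null_p_values_uniform(self):
        """Under random genotypes with no sex effect, Fisher p-values are
        (conservatively) super-uniform: KS should not reject uniformity in
        the anti-conservative direction."""
        rng = np.random.default_rng(12)
        gt = rng.integers(0, 3, size=(2000, 12)).astype(np.int8)
        sites = make_sites(gt, sex=np.array(["F"] * 6 + ["M"] * 6))
        out = dv.sex_diff_scan(sites)
        # discrete exact tests are conservative: P(p <= x) <= x, up to
        # binomial sampling error on the empirical proportion
        m = len(out)
        for x in (0.01, 0.05, 0.1):
            assert (out["p"] <= x).mean() <= x + 3 * np.sqrt(x * (1 - x) / m)
        assert not out["discovery"].any()


class TestVcfRoundTrip:
    def test_read_write_vcf(self, tmp_path, small_sites):
        sites, _ = small_sites
        sub = sites.subset(np.arange(200))
        path = tmp_path / "test.vcf"
        dv.write_vcf(path, sub)
        back = dv.read_vcf(path, sex={s: sx for s, sx in
                                      zip(sub.samples, sub.sex)})
        assert np.array_equal(back.pos, sub.pos)
        assert np.array_equal(back.gt, sub.gt)
        assert np.array_equal(back.anc, sub.anc)
        assert np.array_equal(back.sex, sub.sex)

    def test_sites_tsv_round_trip(self, tmp_path, small_sites):
        sites, _ = small_sites
        sub = sites.subset(np.arange(150))
        path = tmp_path / "sites.tsv"
        dv.write_sites_tsv(path, sub)
        back = dv.read_sites_tsv(path)
        assert np.array_equal(back.gt, sub.gt)
        assert np.array_equal(back.mut_class, sub.mut_class)
        assert np.array_equal(back.cpg, sub.cpg)
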