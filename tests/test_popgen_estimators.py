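import math

import numpy as np
import pytest

from poolscan.popgen_estimators import (
    FreqPair,
    expected_heterozygosity,
    fay_wu_h,
    fst_components,
    fst_multilocus,
    fst_snp,
    polarize,
    subsample_to_uniform_depth,
    tajimas_d,
)

# ---------------------------------------------------------------------------
# brute-force oracles from explicit haplotype matrices


def brute_theta_pi(haps: np.ndarray) -> float:
    """Mean pairwise difference via an explicit loop over haplotype pairs."""
    n = haps.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(haps[i] != haps[j]))
            pairs += 1
    return total / pairs


def brute_tajimas_d(haps: np.ndarray) -> float:
    n, _ = haps.shape
    seg = [c for c in haps.T if 0 < c.sum() < n]
    s = len(seg)
    if s == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (brute_theta_pi(haps) - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def brute_fay_wu_h(haps: np.ndarray) -> float:
    """H from the derived-class site-frequency spectrum, tallied by
    looping over haplotypes (ancestral state is allele 0)."""
    n, L = haps.shape
    t_pi = t_h = 0.0
    for col in haps.T:
        k = int(col.sum())
        if 0 < k < n:
            t_pi += 2 * k * (n - k) / (n * (n - 1))
            t_h += 2 * k * k / (n * (n - 1))
    return t_pi - t_h


# ---------------------------------------------------------------------------


class TestFst:
    def test_nei_hand_value(self):
        fp = FreqPair(p1=0.9, p2=0.1, d1=100, d2=100)
        assert fst_snp(fp, "nei") == pytest.approx((0.5 - 0.18) / 0.5)

    def test_no_differentiation_is_zero(self):
        fp = FreqPair(p1=0.3, p2=0.3, d1=50, d2=50)
        assert fst_snp(fp, "nei") == pytest.approx(0.0)

    def test_monomorphic_site_is_nan(self):
        assert math.isnan(fst_snp(FreqPair(0.0, 0.0, 30, 30), "nei"))

    def test_zero_depth_is_nan(self):
        assert math.isnan(fst_snp(FreqPair(0.5, 0.5, 0, 30)))

    def test_pool_corrected_matches_nei_in_large_sample_limit(self):
        fp = FreqPair(p1=0.9, p2=0.1, d1=10_000, d2=10_000, n1=10_000, n2=10_000)
        nei = fst_snp(fp, "nei")
        corrected = fst_snp(fp, "pool_corrected")
        assert corrected == pytest.approx(nei, rel=0.01)

    def test_pool_corrected_debiases_depth_noise(self):
        """At equal true frequencies, read sampling inflates the naive Nei
        estimate but the corrected estimator centers on zero."""
        rng = np.random.default_rng(11)
        n_snps, depth, n_pool = 4000, 30, 40
        p = 0.3
        pool1 = rng.binomial(n_pool, p, n_snps) / n_pool
        pool2 = rng.binomial(n_pool, p, n_snps) / n_pool
        k = np.column_stack(
            [rng.binomial(depth, pool1), rng.binomial(depth, pool2)]
        )
        d = np.full((n_snps, 2), depth)
        num_c, den_c = fst_components(k, d, (n_pool, n_pool), "pool_corrected")
        num_n, den_n = fst_components(k, d, estimator="nei")
        assert abs(fst_multilocus(num_c, den_c)) < 0.01
        assert fst_multilocus(num_n, den_n) > 0.02  # uncorrected sampling bias

    def test_multilocus_is_ratio_of_sums(self):
        num = np.array([0.1, 0.4])
        den = np.array([0.5, 0.5])
        assert fst_multilocus(num, den) == pytest.approx(0.5)
        # single SNP reduces to the per-SNP ratio; duplication changes nothing
        assert fst_multilocus(num[:1], den[:1]) == pytest.approx(0.2)
        assert fst_multilocus(np.tile(num, 2), np.tile(den, 2)) == pytest.approx(0.5)

    def test_pool_corrected_not_strongly_negative_at_depth20(self):
        rng = np.random.default_rng(5)
        k = rng.integers(0, 21, size=(500, 2))
        d = np.full((500, 2), 20)
        num, den = fst_components(k, d, (40, 28), "pool_corrected")
        with np.errstate(invalid="ignore"):
            per_snp = num / den
        assert np.nanmin(per_snp) > -0.1 or fst_multilocus(num, den) > -0.1


class TestHeterozygosity:
    @pytest.mark.parametrize("p, he", [(0.5, 0.5), (1.0, 0.0), (0.9, 0.18), (0.0, 0.0)])
    def test_values(self, p, he):
        assert expected_heterozygosity(p) == pytest.approx(he)

    def test_bounded_by_half(self):
        p = np.linspace(0, 1, 101)
        he = expected_heterozygosity(p)
        assert np.all(he >= 0) and np.all(he <= 0.5)


class TestSubsampling:
    def test_depth_equal_target_is_identity(self):
        site = subsample_to_uniform_depth(7, 30, target=30, rng=np.random.default_rng(0))
        assert site.k == 7 and site.n == 30

    def test_low_and_high_depths_excluded(self):
        rng = np.random.default_rng(0)
        assert subsample_to_uniform_depth(5, 19, target=30, rng=rng) is None
        assert subsample_to_uniform_depth(5, 400, target=30, max_depth=360, rng=rng) is None

    def test_hypergeometric_mean(self):
        rng = np.random.default_rng(1)
        k = subsample_to_uniform_depth(
            np.full(10_000, 30), np.full(10_000, 60), target=30, rng=rng
        )
        # mean 15, SE of the mean ~ sqrt(30*.25*30/59)/100 ~ 0.02
        assert k.mean() == pytest.approx(15.0, abs=0.1)


class TestTajimasD:
    def test_singleton_hand_value(self):
        # n=4, one singleton: theta_pi=0.5, theta_W=1/a1=0.5455
        d = tajimas_d([1], n=4, min_count=1)
        a1 = 1 + 1 / 2 + 1 / 3
        assert d < 0
        num = 0.5 - 1 / a1
        assert num == pytest.approx(-0.04545, abs=1e-4)

    def test_monomorphic_after_min_count_is_nan(self):
        assert math.isnan(tajimas_d([1, 1, 29, 0], n=30, min_count=2))

    def test_low_covered_fraction_is_nan(self):
        assert math.isnan(tajimas_d([5, 10], n=30, covered_fraction=0.4))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d([1], n=3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_haplotype_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        L = int(rng.integers(1, 21))
        haps = rng.integers(0, 2, size=(n, L))
        counts = haps.sum(axis=0)
        seg = (counts > 0) & (counts < n)
        if not seg.any():
            pytest.skip("no segregating site drawn")
        mine = tajimas_d(counts[seg], n=n, min_count=1)
        assert mine == pytest.approx(brute_tajimas_d(haps), abs=1e-12)


class TestPolarize:
    def test_outgroup_matches_major(self):
        assert polarize("A", "C", 20, 10, "A") == ("C", 10)

    def test_outgroup_matches_minor(self):
        assert polarize("A", "C", 20, 10, "C") == ("A", 20)

    @pytest.mark.parametrize("base", ["G", "N"])
    def test_unusable_outgroup_skips_site(self, base):
        assert polarize("A", "C", 20, 10, base) is None


class TestFayWuH:
    def test_high_frequency_derived_hand_value(self):
        # n=4, k=3: theta_pi=0.5, theta_H=1.5 -> H=-1
        assert fay_wu_h([3], n=4, nolowfreq=0) == pytest.approx(-1.0)

    def test_folded_mirror_flips_excess(self):
        # k=1: theta_pi=0.5, theta_H=1/6 -> +1/3; k=3 mirrors to -1
        assert fay_wu_h([1], n=4, nolowfreq=0) == pytest.approx(1 / 3)
        assert fay_wu_h([3], n=4, nolowfreq=0) == pytest.approx(-1.0)

    def test_nolowfreq_drops_sites_entirely(self):
        with_filter = fay_wu_h([1, 1, 10], n=30, nolowfreq=3)
        only_mid = fay_wu_h([10], n=30, nolowfreq=0)
        assert with_filter == pytest.approx(only_mid)

    def test_no_usable_site_is_nan(self):
        assert math.isnan(fay_wu_h([1, 1], n=30, nolowfreq=3))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_haplotype_matrices(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        L = int(rng.integers(1, 21))
        haps = rng.integers(0, 2, size=(n, L))
        counts = haps.sum(axis=0)
        mine = fay_wu_h(counts, n=n, nolowfreq=0)
        oracle = brute_fay_wu_h(haps)
        if math.isnan(mine):
            assert oracle == 0.0
        else:
            assert mine == pytest.approx(oracle, abs=1e-12)
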