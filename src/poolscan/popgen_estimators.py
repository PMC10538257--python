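"""Per-SNP and windowed population-genetic statistics from pooled counts.

Implements F_ST between reproductive-mode groups (Nei's variance
partition and a pool/depth-corrected identity-probability estimator),
expected heterozygosity, a uniform-depth subsampler, pooled Tajima's D
computed classically on the subsampled counts, and Fay & Wu's H on
outgroup-polarized sites.

Frequencies here are read-level estimates: in Pool-seq the allele
frequency of a pool is estimated by the fraction of reads carrying the
allele, which adds binomial sampling noise on top of the finite number
of chromosomes in the pool. The ``pool_corrected`` F_ST estimator removes
the expectation of both noise layers from the within-group
heterozygosity, so that its multilocus ratio-of-sums converges to the
Nei F_ST of the true pool frequencies.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "FreqPair",
    "SubsampledSite",
    "fst_snp",
    "fst_components",
    "fst_multilocus",
    "expected_heterozygosity",
    "subsample_to_uniform_depth",
    "tajimas_d",
    "polarize",
    "fay_wu_h",
]


@dataclasses.dataclass
class FreqPair:
    """Biallelic site summarized for two groups.

    p1, p2: frequency of one (consistent) allele in each group;
    d1, d2: read depths; n1, n2: pool sizes in chromosomes (2 x lineages).
    """

    p1: float
    p2: float
    d1: int
    d2: int
    n1: int = 0
    n2: int = 0


@dataclasses.dataclass
class SubsampledSite:
    """Allele count at uniform sample size after depth subsampling."""

    k: int  # minor (or derived, if polarized) count
    n: int  # uniform sample size
    polarized: bool = False


# ---------------------------------------------------------------------------
# F_ST


def _nei_components(p1, p2):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)  # = mean(2 p_i (1-p_i))
    pbar = 0.5 * (p1 + p2)
    h_t = 2.0 * pbar * (1.0 - pbar)
    return h_t - h_s, h_t


def _within_het_corrected(k, d, n):
    """Unbiased within-pool heterozygosity from read counts.

    Two distinct reads are identical with probability 1/n + (1 - 1/n) Q,
    Q being the identity of two distinct pool chromosomes, so the
    read-pair identity is debiased by the 1/d (with-replacement read
    draw) and 1/n (same-chromosome collision) terms.
    """
    k = np.asarray(k, dtype=float)
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    m = d - k
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_reads = (k * (k - 1) + m * (m - 1)) / (d * (d - 1))
        q_hat = (pi_reads - 1.0 / n) / (1.0 - 1.0 / n)
    return 1.0 - q_hat


def _pool_corrected_components(k1, d1, n1, k2, d2, n2):
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    h1 = _within_het_corrected(k1, d1, n1)
    h2 = _within_het_corrected(k2, d2, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = k1 / d1
        p2 = k2 / d2
    # between-group heterozygosity is unbiased as-is (independent pools)
    h_b = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    # total het at equal group weights: 2 pbar (1-pbar) = H1/4 + H2/4 + Hb/2
    h_t = 0.25 * (h1 + h2) + 0.5 * h_b
    num = h_t - 0.5 * (h1 + h2)
    return num, h_t


def fst_components(
    minor_counts,
    depths,
    pool_sizes=None,
    estimator: str = "pool_corrected",
):
    """Per-SNP F_ST numerators and denominators for two groups.

    ``minor_counts`` and ``depths`` are (n_snps, 2) arrays (counts of one
    consistent allele and total depths); ``pool_sizes`` is a length-2
    sequence of chromosome pool sizes (required for ``pool_corrected``).
    Returns (num, den) arrays suitable for ratio-of-sums averaging.
    """
    minor_counts = np.atleast_2d(np.asarray(minor_counts, dtype=float))
    depths = np.atleast_2d(np.asarray(depths, dtype=float))
    if estimator == "nei":
        with np.errstate(divide="ignore", invalid="ignore"):
            p = minor_counts / depths
        return _nei_components(p[:, 0], p[:, 1])
    if estimator == "pool_corrected":
        if pool_sizes is None:
            raise ValueError("pool_corrected F_ST requires pool sizes")
        n1, n2 = pool_sizes
        return _pool_corrected_components(
            minor_counts[:, 0], depths[:, 0], n1, minor_counts[:, 1], depths[:, 1], n2
        )
    raise ValueError(f"unknown estimator {estimator!r}")


def fst_snp(fp: FreqPair, estimator: str = "pool_corrected") -> float:
    """F_ST at a single biallelic SNP; NaN when undefined (H_T = 0)."""
    if fp.d1 <= 0 or fp.d2 <= 0:
        return float("nan")
    k = np.array([[fp.p1 * fp.d1, fp.p2 * fp.d2]])
    d = np.array([[fp.d1, fp.d2]])
    pools = (fp.n1, fp.n2) if estimator == "pool_corrected" else None
    num, den = fst_components(k, d, pools, estimator)
    if den[0] <= 0 or not np.isfinite(den[0]):
        return float("nan")
    return float(num[0] / den[0])


def fst_multilocus(num, den) -> float:
    """Ratio-of-sums multilocus F_ST (never mean of per-SNP ratios)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    ok = np.isfinite(num) & np.isfinite(den)
    total = den[ok].sum()
    if total <= 0:
        return float("nan")
    return float(num[ok].sum() / total)


def expected_heterozygosity(p):
    """Nei's expected heterozygosity 1 - p^2 - (1-p)^2 = 2 p (1-p)."""
    p = np.asarray(p, dtype=float)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# uniform-depth subsampling (PoPoolation-style)


def subsample_to_uniform_depth(
    minor_count,
    depth,
    target: int = 30,
    max_depth: int = 360,
    rng: np.random.Generator | None = None,
):
    """Subsample each site to a uniform depth without replacement.

    Sites with depth below ``target`` or above ``max_depth`` are excluded
    (returned count is -1 in the vectorized form). At depth == target the
    counts pass through unchanged; otherwise the subsampled minor count is
    hypergeometric(minor, depth - minor, target).
    """
    if rng is None:
        rng = np.random.default_rng()
    minor_count = np.asarray(minor_count)
    depth = np.asarray(depth)
    scalar = minor_count.ndim == 0
    minor_count = np.atleast_1d(minor_count).astype(np.int64)
    depth = np.atleast_1d(depth).astype(np.int64)
    out = np.full(minor_count.shape, -1, dtype=np.int64)
    keep = (depth >= target) & (depth <= max_depth)
    eq = keep & (depth == target)
    out[eq] = minor_count[eq]
    sub = keep & (depth > target)
    if sub.any():
        out[sub] = rng.hypergeometric(
            minor_count[sub], depth[sub] - minor_count[sub], target
        )
    if scalar:
        k = int(out[0])
        return None if k < 0 else SubsampledSite(k=k, n=target)
    return out


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def theta_pi(counts, n: int) -> float:
    """Tajima's estimator: sum over sites of 2 k (n-k) / (n (n-1))."""
    k = np.asarray(counts, dtype=float)
    return float(np.sum(2.0 * k * (n - k) / (n * (n - 1.0))))


def tajimas_d(
    counts,
    n: int,
    min_count: int = 2,
    covered_fraction: float = 1.0,
    min_covered_fraction: float = 0.5,
) -> float:
    """Tajima's D over a window of uniform-depth sites.

    ``counts`` are per-site allele counts out of ``n`` (either allele of
    the pair; the folded count is used). Sites whose folded count is
    below ``min_count`` are treated as monomorphic; with ``min_count``
    1 this is the classical statistic. For higher thresholds both theta
    estimators are renormalized by the neutral expectation of the
    omitted frequency classes (Achaz-style), otherwise excluding
    singletons would push D strongly positive; the variance is the
    classical one evaluated at the implied total number of segregating
    sites, so the standardization is approximate. Returns NaN when the
    window's covered fraction is below ``min_covered_fraction`` or no
    segregating site remains.
    """
    if n < 4:
        raise ValueError("Tajima's D needs sample size n >= 4")
    if covered_fraction < min_covered_fraction:
        return float("nan")
    k = np.asarray(counts, dtype=np.int64)
    folded = np.minimum(k, n - k)
    seg = folded >= min_count
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    # neutral weight of the frequency classes removed by min_count
    excluded = [
        i for i in range(1, n)
        if min(i, n - i) < min_count
    ]
    a_excl = sum(1.0 / i for i in excluded)
    pi_excl = sum(2.0 * (n - i) / (n * (n - 1.0)) for i in excluded)
    pi = theta_pi(k[seg], n) / (1.0 - pi_excl)
    theta_w = s / (a1 - a_excl)
    s_eff = theta_w * a1
    var = e1 * s_eff + e2 * s_eff * (s_eff - 1)
    if var <= 0:
        return float("nan")
    return float((pi - theta_w) / math.sqrt(var))


# ---------------------------------------------------------------------------
# outgroup polarization and Fay & Wu's H


def polarize(major: str, minor: str, major_count: int, minor_count: int, outgroup: str):
    """Derived-allele count given the outgroup (ancestral proxy) base.

    Returns (derived_allele, derived_count) or None when the outgroup base
    matches neither allele or is N (site unpolarizable).
    """
    if outgroup == "N":
        return None
    if outgroup == major:
        return minor, minor_count
    if outgroup == minor:
        return major, major_count
    return None


def fay_wu_h(derived_counts, n: int, nolowfreq: int = 3) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H over a window.

    ``derived_counts`` are outgroup-polarized derived-allele counts out of
    uniform sample size ``n``. Sites whose folded (minor) count is
    <= ``nolowfreq`` are dropped entirely — a guard against sequencing
    errors masquerading as low- or high-frequency derived variants.
    Returns NaN when no usable site remains.
    """
    k = np.asarray(derived_counts, dtype=np.int64)
    seg = (k >= 1) & (k <= n - 1)
    if nolowfreq > 0:
        folded = np.minimum(k, n - k)
        seg &= folded > nolowfreq
    k = k[seg].astype(float)
    if k.size == 0:
        return float("nan")
    denom = n * (n - 1.0)
    t_pi = np.sum(2.0 * k * (n - k) / denom)
    t_h = np.sum(2.0 * k * k / denom)
    return float(t_pi - t_h)
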