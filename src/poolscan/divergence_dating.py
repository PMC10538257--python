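"""Dating the split of the two allelic classes at the candidate region.

Three estimators, each biased in its own way, are computed side by side:

1. net-divergence dating, T = D_a / (2 mu), where D_a is the raw
   between-mode divergence minus the mean within-mode diversity and mu
   the mean annual substitution rate of the two modes;
2. substitution-count dating, T = N_mutated / (2 N_sites mu), where
   N_mutated counts differences between consensus sequences drawn
   allele-by-allele from the pooled frequencies (replicated to get a
   confidence interval);
3. synonymous-divergence dating, T = (dS / dS_cal) T_cal, scaling the
   median per-gene dS between the two consensus alleles by a calibrated
   interspecies synonymous divergence.

The annual rates combine a per-parthenogenetic-generation rate with a
per-sexual-generation rate: an obligate parthenogen runs N_gen asexual
generations a year (mu_op = N_gen * mu_parth) while a cyclical
parthenogen replaces one of them with a sexual generation
(mu_cp = (N_gen - 1) * mu_parth + mu_sex).

dS uses the Nei–Gojobori (1986) pathway-counting method with the
Jukes–Cantor correction; mutations creating stop codons count as
nonsynonymous when counting sites, and substitution pathways passing
through a stop codon are excluded when counting differences.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
import math
import warnings

import numpy as np

from .io_formats import GeneModel

__all__ = [
    "MutationRates",
    "DivergenceEstimate",
    "ConsensusPair",
    "compose_mutation_rates",
    "net_divergence_da",
    "time_from_da",
    "draw_consensus",
    "count_substitutions",
    "time_from_counts",
    "ng86_counts",
    "ds_ng86",
    "pairwise_ds",
    "time_from_ds",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_AA = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    _CODON_AA[_a + _b + _c] = _AA[_i]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# mutation-rate composition


@dataclasses.dataclass
class MutationRates:
    """Per-generation inputs and the derived annual substitution rates.

    All rates are substitutions per site; CIs are (low, high) tuples
    obtained by pushing the input bounds through the same formulas.
    """

    mu_parth: float
    mu_parth_ci: tuple[float, float]
    mu_sex: float
    mu_sex_ci: tuple[float, float]
    n_gen: int
    mu_op: float = 0.0
    mu_op_ci: tuple[float, float] = (0.0, 0.0)
    mu_cp: float = 0.0
    mu_cp_ci: tuple[float, float] = (0.0, 0.0)
    mu_mean: float = 0.0
    mu_mean_ci: tuple[float, float] = (0.0, 0.0)


def compose_mutation_rates(
    mu_parth: float = 2.7e-10,
    mu_parth_ci: tuple[float, float] = (1.9e-10, 3.5e-10),
    mu_sex: float = 2.96e-9,
    mu_sex_ci: tuple[float, float] = (1.52e-9, 4.99e-9),
    n_gen: int = 15,
) -> MutationRates:
    """Annual substitution rates for the OP and CP life cycles.

    mu_op = N_gen * mu_parth; mu_cp = (N_gen - 1) * mu_parth + mu_sex;
    the rate used for dating is their mean. CI bounds are composed by
    applying the same formulas to the bound values.
    """

    def per_year(mp: float, ms: float) -> tuple[float, float, float]:
        op = n_gen * mp
        cp = (n_gen - 1) * mp + ms
        return op, cp, 0.5 * (op + cp)

    op, cp, mean = per_year(mu_parth, mu_sex)
    op_lo, cp_lo, mean_lo = per_year(mu_parth_ci[0], mu_sex_ci[0])
    op_hi, cp_hi, mean_hi = per_year(mu_parth_ci[1], mu_sex_ci[1])
    return MutationRates(
        mu_parth=mu_parth,
        mu_parth_ci=mu_parth_ci,
        mu_sex=mu_sex,
        mu_sex_ci=mu_sex_ci,
        n_gen=n_gen,
        mu_op=op,
        mu_op_ci=(op_lo, op_hi),
        mu_cp=cp,
        mu_cp_ci=(cp_lo, cp_hi),
        mu_mean=mean,
        mu_mean_ci=(mean_lo, mean_hi),
    )


@dataclasses.dataclass
class DivergenceEstimate:
    """One dating result: method tag, point estimate in years, 95% CI
    and the inputs it was computed from."""

    method: str  # 'da' | 'substitution_count' | 'ds_calibrated'
    t_years: float
    ci95: tuple[float, float]
    inputs: dict

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.t_years <= hi):
            raise ValueError("CI does not bracket the point estimate")


# ---------------------------------------------------------------------------
# approach 1: net divergence


def net_divergence_da(p_op: np.ndarray, p_cp: np.ndarray) -> float:
    """Net divergence D_a = D_xy - (pi_op + pi_cp) / 2 over callable sites.

    Inputs are derived (or any consistently chosen) allele frequencies
    at every callable site, zeros included for monomorphic positions.
    """
    p1 = np.asarray(p_op, dtype=float)
    p2 = np.asarray(p_cp, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("frequency tracks differ in length")
    d_xy = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
    pi1 = np.mean(2 * p1 * (1 - p1))
    pi2 = np.mean(2 * p2 * (1 - p2))
    return float(d_xy - 0.5 * (pi1 + pi2))


def time_from_da(
    da: float,
    rates: MutationRates,
    da_ci: tuple[float, float] | None = None,
) -> DivergenceEstimate:
    """T = D_a / (2 mu); CI pairs low D_a with high mu and vice versa."""
    if da_ci is None:
        da_ci = (da, da)
    t = da / (2 * rates.mu_mean)
    lo = da_ci[0] / (2 * rates.mu_mean_ci[1])
    hi = da_ci[1] / (2 * rates.mu_mean_ci[0])
    return DivergenceEstimate(
        method="da",
        t_years=t,
        ci95=(lo, hi),
        inputs={"da": da, "mu_mean": rates.mu_mean, "mu_mean_ci": rates.mu_mean_ci},
    )


# ---------------------------------------------------------------------------
# approach 2: consensus substitutions


@dataclasses.dataclass
class ConsensusPair:
    """One replicate pair of mode consensus sequences over the region.

    Sequences are region-relative; ``mask`` marks callable positions
    (depth >= 20 in every population) — substitutions are only counted
    there.
    """

    op_seq: str
    cp_seq: str
    mask: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        if len(self.op_seq) != len(self.cp_seq) or len(self.op_seq) != self.mask.size:
            raise ValueError("consensus sequences and mask differ in length")


def draw_consensus(
    p_op: np.ndarray,
    p_cp: np.ndarray,
    region_seq: str,
    snp_offsets: np.ndarray,
    derived_bases: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    seed: int | None = None,
) -> ConsensusPair:
    """One haploid consensus per mode by Bernoulli draws at SNPs.

    At each polymorphic site one allele is drawn per mode with
    probability equal to its frequency in that mode's pool; monomorphic
    callable sites copy the region sequence. ``snp_offsets`` are
    region-relative positions of the SNPs, ``region_seq`` the ancestral
    sequence of the region.
    """
    p_op = np.asarray(p_op, dtype=float)
    p_cp = np.asarray(p_cp, dtype=float)
    op = np.frombuffer(region_seq.encode(), dtype="S1").copy()
    cp = op.copy()
    der = np.asarray(derived_bases, dtype="S1")
    take_op = rng.random(p_op.size) < p_op
    take_cp = rng.random(p_cp.size) < p_cp
    op[snp_offsets[take_op]] = der[take_op]
    cp[snp_offsets[take_cp]] = der[take_cp]
    return ConsensusPair(
        op_seq=op.tobytes().decode(),
        cp_seq=cp.tobytes().decode(),
        mask=np.asarray(mask, dtype=bool),
        seed=seed,
    )


def count_substitutions(pair: ConsensusPair) -> int:
    """Hamming distance between the consensus pair on the callable mask."""
    a = np.frombuffer(pair.op_seq.encode(), dtype="S1")
    b = np.frombuffer(pair.cp_seq.encode(), dtype="S1")
    return int(np.sum((a != b) & pair.mask))


def time_from_counts(
    n_mutated,
    n_sites: int,
    rates: MutationRates,
) -> DivergenceEstimate:
    """T = N_mutated / (2 N_sites mu).

    ``n_mutated`` may be a scalar or the per-replicate counts from
    repeated consensus draws; with replicates the point estimate uses
    their mean and the CI combines the 2.5/97.5 replicate percentiles of
    N with the mutation-rate CI conservatively (low N with high mu, high
    N with low mu). N-only and mu-only intervals are reported alongside.
    """
    n = np.atleast_1d(np.asarray(n_mutated, dtype=float))
    n_point = float(n.mean())
    if n.size > 1:
        n_lo, n_hi = (float(x) for x in np.percentile(n, [2.5, 97.5]))
    else:
        n_lo = n_hi = n_point
    denom = 2.0 * n_sites
    t = n_point / (denom * rates.mu_mean)
    lo = n_lo / (denom * rates.mu_mean_ci[1])
    hi = n_hi / (denom * rates.mu_mean_ci[0])
    return DivergenceEstimate(
        method="substitution_count",
        t_years=t,
        ci95=(lo, hi),
        inputs={
            "n_mutated_sites": n_point,
            "n_mutated_ci": (n_lo, n_hi),
            "n_sites": n_sites,
            "mu_mean": rates.mu_mean,
            "mu_mean_ci": rates.mu_mean_ci,
            "ci_n_only": (n_lo / (denom * rates.mu_mean), n_hi / (denom * rates.mu_mean)),
            "ci_mu_only": (
                n_point / (denom * rates.mu_mean_ci[1]),
                n_point / (denom * rates.mu_mean_ci[0]),
            ),
            "n_replicates": int(n.size),
        },
    )


# ---------------------------------------------------------------------------
# approach 3: synonymous divergence (NG86)


@functools.lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Synonymous sites of a codon: at each position, the fraction of the
    three possible changes that keep the amino acid (changes to stop
    codons count as nonsynonymous)."""
    aa = _CODON_AA[codon]
    syn = 0.0
    for i in range(3):
        for alt in "ACGT":
            if alt == codon[i]:
                continue
            mut = codon[:i] + alt + codon[i + 1 :]
            if _CODON_AA[mut] == aa and _CODON_AA[mut] != "*":
                syn += 1.0
    return syn / 3.0


@functools.lru_cache(maxsize=None)
def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over substitution pathways; pathways visiting a stop codon
    are excluded unless every pathway does."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_AA[nxt] == "*" and nxt != c2:
                blocked = True
            if _CODON_AA[nxt] == _CODON_AA[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def ng86_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """Nei–Gojobori site and difference counts for an aligned CDS pair.

    Returns (S_sites, N_sites, S_diff, N_diff). Codons containing
    non-ACGT characters, and codon pairs where either codon is a stop,
    are skipped. Sequences must be aligned, in frame and equal length.
    """
    if len(seq1) != len(seq2):
        raise ValueError("CDS pair not aligned (unequal lengths)")
    n_codons = len(seq1) // 3
    s_sites = n_sites = s_diff = n_diff = 0.0
    for i in range(n_codons):
        c1 = seq1[3 * i : 3 * i + 3].upper()
        c2 = seq2[3 * i : 3 * i + 3].upper()
        if any(b not in "ACGT" for b in c1 + c2):
            continue
        if _CODON_AA[c1] == "*" or _CODON_AA[c2] == "*":
            continue
        s1, s2 = _syn_site_fraction(c1), _syn_site_fraction(c2)
        s_sites += 0.5 * (s1 + s2)
        n_sites += 3.0 - 0.5 * (s1 + s2)
        sd, nd = _pathway_differences(c1, c2)
        s_diff += sd
        n_diff += nd
    return s_sites, n_sites, s_diff, n_diff


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ds_ng86(seq1: str, seq2: str) -> float:
    """Jukes–Cantor-corrected synonymous divergence of an aligned CDS pair."""
    s_sites, _, s_diff, _ = ng86_counts(seq1, seq2)
    if s_sites <= 0:
        return float("nan")
    return _jukes_cantor(s_diff / s_sites)


def _extract_cds(seq: str, gene: GeneModel, region_start: int) -> str | None:
    """Spliced CDS of a gene from a region-relative sequence; None when
    the gene extends beyond the region."""
    parts = []
    for s, e in gene.cds:
        s0, e0 = s - region_start, e - region_start
        if s0 < 0 or e0 > len(seq):
            return None
        parts.append(seq[s0:e0])
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return cds[gene.phase :]


def _has_internal_stop(cds: str) -> bool:
    n_codons = len(cds) // 3
    for i in range(n_codons - 1):
        codon = cds[3 * i : 3 * i + 3]
        if _CODON_AA.get(codon) == "*":
            return True
    return False


def pairwise_ds(
    pair: ConsensusPair,
    genes: list[GeneModel],
    region_start: int,
    method: str = "NG86",
) -> tuple[float, dict[str, float]]:
    """Median synonymous divergence between the consensus alleles over
    the region's genes.

    Genes with a broken frame, lying partly outside the region, or
    acquiring a premature stop in either consensus are skipped with a
    warning. Returns (median_dS, per-gene dS). Raises if no gene is
    usable.
    """
    if method != "NG86":
        raise ValueError(f"unsupported dS method {method!r}")
    per_gene: dict[str, float] = {}
    for gene in genes:
        if not gene.usable:
            warnings.warn(f"{gene.gene_id}: broken reading frame, skipped")
            continue
        cds_op = _extract_cds(pair.op_seq, gene, region_start)
        cds_cp = _extract_cds(pair.cp_seq, gene, region_start)
        if cds_op is None or cds_cp is None:
            continue
        if _has_internal_stop(cds_op) or _has_internal_stop(cds_cp):
            warnings.warn(f"{gene.gene_id}: premature stop codon, skipped")
            continue
        ds = ds_ng86(cds_op, cds_cp)
        if math.isfinite(ds):
            per_gene[gene.gene_id] = ds
    if not per_gene:
        raise ValueError("no usable gene for dS estimation")
    return float(np.median(list(per_gene.values()))), per_gene


def time_from_ds(
    ds: float,
    ds_cal: float = 0.2268,
    t_cal: float = 22e6,
    ds_ci: tuple[float, float] | None = None,
) -> DivergenceEstimate:
    """T = (dS / dS_cal) * T_cal, proportionality against a calibrated
    interspecies synonymous divergence."""
    if ds_ci is None:
        ds_ci = (ds, ds)
    scale = t_cal / ds_cal
    return DivergenceEstimate(
        method="ds_calibrated",
        t_years=ds * scale,
        ci95=(ds_ci[0] * scale, ds_ci[1] * scale),
        inputs={"ds": ds, "ds_ci": ds_ci, "ds_cal": ds_cal, "t_cal": t_cal},
    )
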