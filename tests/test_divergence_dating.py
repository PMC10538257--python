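import itertools
import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from poolscan.divergence_dating import (
    ConsensusPair,
    compose_mutation_rates,
    count_substitutions,
    draw_consensus,
    ds_ng86,
    net_divergence_da,
    ng86_counts,
    pairwise_ds,
    time_from_counts,
    time_from_da,
    time_from_ds,
)
from poolscan.io_formats import GeneModel

# amino-acid map taken from Biopython, independent of the implementation
AA = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    AA[stop] = "*"
SENSE = sorted(c for c, a in AA.items() if a != "*")


class TestMutationRates:
    def test_printed_central_rate_and_ci(self):
        r = compose_mutation_rates()
        # printed precision is 3 significant digits
        assert r.mu_mean == pytest.approx(5.39e-9, abs=0.005e-9 + 1e-15)
        assert r.mu_mean_ci[0] == pytest.approx(3.52e-9, abs=0.005e-9 + 1e-15)
        assert r.mu_mean_ci[1] == pytest.approx(7.57e-9, abs=0.005e-9 + 1e-15)

    def test_component_identities(self):
        r = compose_mutation_rates()
        assert r.mu_op == pytest.approx(r.n_gen * r.mu_parth)
        assert r.mu_cp == pytest.approx((r.n_gen - 1) * r.mu_parth + r.mu_sex)
        assert r.mu_mean == pytest.approx(0.5 * (r.mu_op + r.mu_cp))
        assert r.mu_mean_ci[0] < r.mu_mean < r.mu_mean_ci[1]

    def test_equal_generation_rates_collapse(self):
        mu = 1e-9
        r = compose_mutation_rates(mu, (mu, mu), mu, (mu, mu), n_gen=15)
        assert r.mu_cp == pytest.approx(r.mu_op) == pytest.approx(15 * mu)


class TestNetDivergence:
    def test_fixed_differences_give_fraction(self):
        n = 1000
        p_op = np.zeros(n)
        p_cp = np.zeros(n)
        p_cp[:100] = 1.0  # 10% fixed differences, no polymorphism
        assert net_divergence_da(p_op, p_cp) == pytest.approx(0.1)

    def test_identical_tracks_give_zero(self):
        p = np.random.default_rng(0).random(500)
        assert net_divergence_da(p, p) == pytest.approx(
            0.0, abs=1e-12
        ) or net_divergence_da(p, p) == pytest.approx(
            np.mean(2 * p * (1 - p)) - np.mean(2 * p * (1 - p)), abs=1e-12
        )

    def test_hand_value_single_polymorphic_site(self):
        # one site p1=0.9, p2=0.1 among 10 callable sites:
        # D_xy = (0.9*0.9 + 0.1*0.1)/10 = 0.082, mean pi = 0.018
        p1 = np.zeros(10)
        p2 = np.zeros(10)
        p1[0], p2[0] = 0.9, 0.1
        assert net_divergence_da(p1, p2) == pytest.approx(0.082 - 0.018)


class TestTimeFromDa:
    def test_arithmetic(self):
        r = compose_mutation_rates(1e-9, (1e-9, 1e-9), 1e-9, (1e-9, 1e-9), n_gen=5)
        # mu_mean = 5e-9 exactly under equal rates with n_gen=5
        est = time_from_da(1e-3, r)
        assert est.t_years == pytest.approx(1e5)

    def test_zero_da_is_zero(self):
        est = time_from_da(0.0, compose_mutation_rates())
        assert est.t_years == 0.0

    def test_doubling_mu_halves_t(self):
        r1 = compose_mutation_rates(1e-10, (1e-10, 1e-10), 1e-10, (1e-10, 1e-10))
        r2 = compose_mutation_rates(2e-10, (2e-10, 2e-10), 2e-10, (2e-10, 2e-10))
        da = 5e-4
        assert time_from_da(da, r1).t_years == pytest.approx(
            2 * time_from_da(da, r2).t_years
        )


def _pair(op, cp, mask=None):
    if mask is None:
        mask = np.ones(len(op), dtype=bool)
    return ConsensusPair(op_seq=op, cp_seq=cp, mask=mask)


class TestConsensus:
    def _draw(self, p_op, p_cp, seed=0):
        n = len(p_op)
        region = "A" * n
        return draw_consensus(
            np.array(p_op), np.array(p_cp), region,
            np.arange(n), np.array(["G"] * n), np.ones(n, dtype=bool),
            np.random.default_rng(seed),
        )

    def test_fixed_frequency_fixes_allele(self):
        pair = self._draw([1.0] * 20, [0.0] * 20)
        assert pair.op_seq == "G" * 20 and pair.cp_seq == "A" * 20

    def test_intermediate_frequencies_differ_half_the_time(self):
        n = 20_000
        pair = self._draw([0.5] * n, [0.5] * n, seed=1)
        diff = count_substitutions(pair)
        # P(differ) = p(1-q) + q(1-p) = 0.5; SE ~ sqrt(n)/2
        assert diff / n == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(n))

    def test_same_seed_identical_pair(self):
        a = self._draw([0.3] * 50, [0.7] * 50, seed=9)
        b = self._draw([0.3] * 50, [0.7] * 50, seed=9)
        assert a.op_seq == b.op_seq and a.cp_seq == b.cp_seq

    def test_count_substitutions_respects_mask(self):
        mask = np.array([True, True, False, True])
        pair = _pair("ACGT", "ACCA", mask)  # diffs at offsets 2 (masked) and 3
        assert count_substitutions(pair) == 1
        assert count_substitutions(_pair("ACGT", "ACGT")) == 0

    def test_planted_differences_counted(self):
        op = list("A" * 30)
        for i in (3, 11, 27):
            op[i] = "T"
        assert count_substitutions(_pair("".join(op), "A" * 30)) == 3

    def test_expected_substitutions_match_closed_form(self):
        """E[N_mutated] over seeds equals sum p(1-q) + q(1-p)."""
        rng = np.random.default_rng(42)
        n = 10_000
        p_op = rng.random(n)
        p_cp = rng.random(n)
        expected = float(np.sum(p_op * (1 - p_cp) + p_cp * (1 - p_op)))
        counts = []
        for seed in range(200):
            pair = draw_consensus(
                p_op, p_cp, "A" * n, np.arange(n), np.array(["G"] * n),
                np.ones(n, dtype=bool), np.random.default_rng(1000 + seed),
            )
            counts.append(count_substitutions(pair))
        counts = np.array(counts)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se


class TestTimeFromCounts:
    def test_printed_inputs_reproduce_printed_age(self):
        est = time_from_counts(4_442, 740_918, compose_mutation_rates())
        assert est.t_years == pytest.approx(555_719, rel=0.005)

    def test_zero_substitutions_zero_age(self):
        assert time_from_counts(0, 1000, compose_mutation_rates()).t_years == 0.0

    def test_linear_in_n(self):
        r = compose_mutation_rates()
        t1 = time_from_counts(100, 10_000, r).t_years
        t2 = time_from_counts(300, 10_000, r).t_years
        assert t2 == pytest.approx(3 * t1)

    def test_replicate_ci_brackets_and_reports_components(self):
        r = compose_mutation_rates()
        reps = np.random.default_rng(0).poisson(500, size=100)
        est = time_from_counts(reps, 100_000, r)
        assert est.ci95[0] <= est.t_years <= est.ci95[1]
        lo_n, hi_n = est.inputs["ci_n_only"]
        lo_m, hi_m = est.inputs["ci_mu_only"]
        # conservative combination is at least as wide as each component
        assert est.ci95[0] <= min(lo_n, lo_m) and est.ci95[1] >= max(hi_n, hi_m)

    def test_recovers_simulation_age_under_jukes_cantor(self):
        """Two sequences diverged T* years at rate mu; the count
        estimator recovers T* within 2 SE while T*mu is small."""
        rng = np.random.default_rng(8)
        n_sites, t_true = 100_000, 1_000_000
        mu = 5e-9
        r = compose_mutation_rates(mu / 15, (mu / 15,) * 2, mu / 15, (mu / 15,) * 2)
        assert r.mu_mean == pytest.approx(mu)
        p_hit = 1.0 - math.exp(-mu * t_true)  # per branch
        seq = rng.integers(0, 4, n_sites)
        a, b = seq.copy(), seq.copy()
        for s in (a, b):
            hit = rng.random(n_sites) < p_hit
            s[hit] = (s[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
        n_diff = int((a != b).sum())
        est = time_from_counts(n_diff, n_sites, r)
        se = math.sqrt(n_diff) / (2 * n_sites * mu)
        assert abs(est.t_years - t_true) < 2 * se


# ---------------------------------------------------------------------------
# NG86 oracle: per-codon enumeration written from scratch


def oracle_syn_sites(codon):
    syn = 0
    for i, ref in enumerate(codon):
        for alt in "ACGT":
            if alt == ref:
                continue
            mut = codon[:i] + alt + codon[i + 1 :]
            if AA[mut] != "*" and AA[mut] == AA[codon]:
                syn += 1
    return syn / 3


def oracle_path_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(positions):
        sd = nd = 0
        cur = c1
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if AA[nxt] == "*" and nxt != c2:
                ok = False
            if AA[nxt] == AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, ok))
    usable = [(s, n) for s, n, ok in results if ok] or [
        (s, n) for s, n, _ in results
    ]
    return (
        sum(s for s, _ in usable) / len(usable),
        sum(n for _, n in usable) / len(usable),
    )


class TestNg86:
    def test_all_sense_codon_pairs_match_bruteforce(self):
        for c1 in SENSE:
            for c2 in SENSE:
                s_sites, n_sites, sd, nd = ng86_counts(c1, c2)
                exp_sites = (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2
                exp_sd, exp_nd = oracle_path_diffs(c1, c2)
                assert s_sites == pytest.approx(exp_sites, abs=1e-12), (c1, c2)
                assert sd == pytest.approx(exp_sd, abs=1e-12), (c1, c2)
                assert nd == pytest.approx(exp_nd, abs=1e-12), (c1, c2)

    def test_identical_cds_zero_ds(self):
        assert ds_ng86("ATGAAACTT", "ATGAAACTT") == 0.0

    def test_hand_counted_synonymous_change(self):
        # ATG AAA CTT vs ATG AAA CTA: one synonymous third-position change.
        # Hand NG86 site count: S(ATG)=0, S(AAA)=1/3, S(CTT)=1, S(CTA)=4/3
        # -> S = 0 + 1/3 + (1 + 4/3)/2 = 3/2; Sd = 1.
        s_sites, _, sd, nd = ng86_counts("ATGAAACTT", "ATGAAACTA")
        assert s_sites == pytest.approx(1.5)
        assert (sd, nd) == (1.0, 0.0)
        p = 1 / 1.5
        assert ds_ng86("ATGAAACTT", "ATGAAACTA") == pytest.approx(
            -0.75 * math.log(1 - 4 * p / 3)
        )

    def test_nonsynonymous_only_change_gives_zero_ds(self):
        # AAA (K) -> GAA (E), first position, nonsynonymous
        assert ds_ng86("ATGAAACTT", "ATGGAACTT") == 0.0


class TestPairwiseDs:
    def _region(self):
        #          0123456789012345678
        region = "AAATGAAACTTTGGTAAAA"  # gene CDS at [2, 17): ATGAAACTTTGGTAA
        gene = GeneModel("g1", "X", "+", [(2, 17)])
        return region, gene

    def test_single_synonymous_difference(self):
        region, gene = self._region()
        other = region[:10] + "A" + region[11:]  # CTT -> CTA
        med, per_gene = pairwise_ds(
            _pair(region, other), [gene], region_start=0
        )
        assert per_gene["g1"] > 0 and med == per_gene["g1"]

    def test_premature_stop_skips_gene(self):
        region, gene = self._region()
        broken = region[:5] + "TAA" + region[8:]  # AAA -> TAA mid-CDS
        with pytest.warns(UserWarning, match="premature stop"):
            with pytest.raises(ValueError, match="no usable gene"):
                pairwise_ds(_pair(region, broken), [gene], region_start=0)

    def test_reverse_strand_gene(self):
        from poolscan.divergence_dating import reverse_complement

        cds = "ATGAAAAAACTTTGGTAA"
        region = "GG" + reverse_complement(cds) + "CC"
        gene = GeneModel("g1", "X", "-", [(2, 20)])
        # synonymous change CTT->CTC on the coding strand
        cds2 = "ATGAAAAAACTCTGGTAA"
        region2 = "GG" + reverse_complement(cds2) + "CC"
        med, _ = pairwise_ds(_pair(region, region2), [gene], region_start=0)
        assert med > 0


class TestTimeFromDs:
    def test_printed_calibration_value(self):
        est = time_from_ds(0.00531)
        assert est.t_years == pytest.approx(515_437, rel=0.002)

    def test_zero_ds_zero_age(self):
        assert time_from_ds(0.0).t_years == 0.0

    def test_calibration_identity(self):
        assert time_from_ds(0.2268).t_years == pytest.approx(22e6)
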