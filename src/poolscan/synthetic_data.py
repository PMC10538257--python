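"""Ground-truth allele-frequency landscapes and Pool-seq samples drawn
from them, so that every downstream stage of the scan is testable without
external sequencing data.

The generator emulates the study design it is modeled on: six pooled
populations (three cyclically parthenogenetic, CP, and three obligately
parthenogenetic, OP), two replicate sequencing libraries per population
drawn from one DNA pool, modest per-library depth, a weakly
differentiated genomic background, and a single X-linked candidate
region where the two reproductive modes are strongly differentiated and
OP diversity is reduced.

Frequency model
---------------
Background sites share an ancestral frequency drawn from a neutral
(1/i) site-frequency spectrum; each mode's frequency is then a Beta
perturbation of it calibrated so that the expected multilocus Nei F_ST
between modes equals ``background_fst``. Candidate sites put the OP
pool near fixation for one allele (matching the target OP
heterozygosity) and place the CP frequency at the value that yields the
target per-site Nei F_ST.

Read sampling is two-stage: lineage chromosomes are drawn binomially
from the population frequency into the finite DNA pool (2 x lineages
chromosomes, shared by replicate libraries), then reads are drawn
binomially from the realized pool frequency at a Poisson depth per
library. Pool-size corrections in the estimators are therefore
exercised, not just depth noise.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    BASE_TO_COL,
    GeneModel,
    PoolMetadata,
    SyncData,
    write_fasta,
    write_gff3,
    write_sync,
)

BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate(BASES)}  # index into BASES, not sync columns
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# sense codons only; used to synthesize stop-free coding sequence
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclasses.dataclass
class TruthConfig:
    """Parameters of the simulated study.

    Defaults mirror the emulated design: 4 chromosomes (X first) of 2 Mb,
    3 populations per mode with 20 (CP) / 14 (OP) lineages per pool, two
    replicate libraries per population at ~18x each, a 200-kb X-linked
    candidate region, background between-mode F_ST 0.025, candidate
    F_ST 0.35 with OP heterozygosity 0.14, and an outgroup diverged 1%.
    """

    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    n_pops_per_mode: int = 3
    lineages_per_pool: dict = dataclasses.field(
        default_factory=lambda: {"CP": 20, "OP": 14}
    )
    mean_depth_per_library: float = 18.0
    candidate_interval: tuple = ("X", 900_000, 1_100_000)
    background_fst: float = 0.025
    candidate_fst: float = 0.35
    candidate_he_op: float = 0.14
    within_mode_fst: float = 0.0
    snp_density: float = 0.01
    outgroup_divergence: float = 0.01
    n_candidate_genes: int = 30
    n_background_genes_per_chrom: int = 5
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return ["X"] + [f"A{i}" for i in range(1, self.n_chromosomes)]

    def validate(self) -> None:
        for name in ("background_fst", "candidate_fst", "candidate_he_op",
                     "within_mode_fst", "outgroup_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.candidate_he_op > 0.5:
            raise ValueError("candidate_he_op cannot exceed 0.5 (biallelic)")
        chrom, start, end = self.candidate_interval
        if chrom not in self.chrom_names():
            raise ValueError(f"candidate chromosome {chrom!r} not in genome")
        if not (0 <= start < end <= self.chrom_length):
            raise ValueError("candidate interval outside its chromosome")


@dataclasses.dataclass
class TruthState:
    """Everything the generator knows: the landscape downstream stages
    must recover."""

    config: TruthConfig
    chrom_lengths: dict[str, int]
    ref_seqs: dict[str, np.ndarray]  # base indices 0..3 into BASES
    site_chrom: np.ndarray
    site_pos: np.ndarray  # 0-based
    anc_base: np.ndarray
    der_base: np.ndarray
    is_candidate: np.ndarray
    pop_freqs: np.ndarray  # (n_sites, n_pops) derived-allele frequencies
    pop_ids: list[str]
    pop_modes: list[str]
    genes: list[GeneModel]

    def reference(self) -> dict[str, str]:
        return {c: "".join(BASES[s]) for c, s in self.ref_seqs.items()}


# ---------------------------------------------------------------------------
# frequency-model calibration


def _neutral_sfs_freqs(rng: np.random.Generator, n_sites: int, m: int = 40) -> np.ndarray:
    """Derived-allele frequencies i/m with P(i) proportional to 1/i."""
    i = np.arange(1, m)
    w = 1.0 / i
    w /= w.sum()
    return rng.choice(i, size=n_sites, p=w) / m


def _beta_fst_param(target_fst: float) -> float:
    """Beta dispersion F* such that expected two-group Nei F_ST = target.

    For two groups drawn iid from Beta(mean p0, dispersion F), the
    expected heterozygosity components give a multilocus Nei F_ST of
    (F/2) / (1 - F/2); inverting yields F* = 2 f / (1 + f).
    """
    return 2.0 * target_fst / (1.0 + target_fst)


def _nei_fst_site(p1: float, p2: float) -> float:
    h_s = p1 * (1 - p1) + p2 * (1 - p2)
    pbar = 0.5 * (p1 + p2)
    h_t = 2 * pbar * (1 - pbar)
    return 1.0 - h_s / h_t if h_t > 0 else float("nan")


def _candidate_cp_freq(target_fst: float, eps: float) -> float:
    """CP derived-allele frequency giving the target per-site Nei F_ST
    when the OP pool sits at frequency 1 - eps."""
    f = lambda q: _nei_fst_site(1.0 - eps, q) - target_fst
    lo, hi = 1e-3, 1.0 - eps - 1e-3
    if f(lo) < 0:  # target unreachable given OP residual diversity
        raise ValueError(
            f"candidate_fst={target_fst} unreachable with candidate_he_op giving eps={eps:.3g}"
        )
    return float(brentq(f, lo, hi))


def _he_to_eps(he: float) -> float:
    """Distance from fixation with expected heterozygosity ``he``."""
    return 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * he))


# ---------------------------------------------------------------------------
# truth construction


def _avoid_nonsense_alleles(genes, site_chrom, site_pos, anc_base, der_base, ref, rng):
    """Re-draw derived alleles that would create premature stop codons.

    Purifying selection keeps nonsense variants from segregating at
    appreciable frequency, so coding SNPs get a derived base that keeps
    the codon sense whenever one exists.
    """
    from .divergence_dating import _CODON_AA
    from .variant_effects import _coding_offset

    comp = _COMPLEMENT
    for gene in genes:
        s, e = gene.span
        sel = np.flatnonzero(
            (site_chrom == gene.chrom) & (site_pos >= s) & (site_pos < e)
        )
        if sel.size == 0:
            continue
        cds = "".join(
            "".join(BASES[ref[gene.chrom][a:b]]) for a, b in gene.cds
        )
        if gene.strand == "-":
            cds = "".join(comp[b] for b in reversed(cds))
        for i in sel:
            off = _coding_offset(gene, int(site_pos[i]))
            if off is None or off >= len(cds):
                continue
            ci, cp = divmod(off, 3)
            codon = cds[3 * ci : 3 * ci + 3]
            if len(codon) < 3 or _CODON_AA.get(codon) == "*":
                continue  # terminal stop codon: leave as drawn
            choices = [b for b in "ACGT" if b != anc_base[i]]
            rng.shuffle(choices)
            for b in choices:
                alt = b if gene.strand == "+" else comp[b]
                mut = codon[:cp] + alt + codon[cp + 1 :]
                if _CODON_AA.get(mut) != "*":
                    der_base[i] = b
                    break


def _draw_gene(rng, chrom, lo, hi, idx, ref_seq):
    """Place one stop-free gene in [lo, hi); returns None if it won't fit."""
    n_exons = int(rng.integers(1, 4))
    exon_lens = rng.integers(60, 201, size=n_exons) * 3
    intron_lens = rng.integers(80, 301, size=max(n_exons - 1, 0))
    total = int(exon_lens.sum() + intron_lens.sum())
    if hi - lo < total:
        return None
    start = int(rng.integers(lo, hi - total + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    cds = []
    pos = start
    for i, el in enumerate(exon_lens):
        cds.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    n_codons = int(exon_lens.sum()) // 3
    codons = ["ATG"] + list(rng.choice(_SENSE_CODONS, size=n_codons - 2)) + ["TAA"]
    coding = "".join(codons)
    if strand == "-":
        coding = "".join(_COMPLEMENT[b] for b in reversed(coding))
    base_idx = np.array([_BASE_IDX[b] for b in coding])
    offset = 0
    for s, e in cds:
        ref_seq[s:e] = base_idx[offset : offset + e - s]
        offset += e - s
    return GeneModel(gene_id=f"gene_{chrom}_{idx}", chrom=chrom, strand=strand, cds=cds)


def build_truth(config: TruthConfig) -> TruthState:
    """Draw the ground-truth landscape a scan should recover."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = config.chrom_names()
    lengths = {c: config.chrom_length for c in chroms}
    ref = {c: rng.integers(0, 4, size=lengths[c]).astype(np.int8) for c in chroms}

    cand_chrom, cand_start, cand_end = config.candidate_interval
    genes: list[GeneModel] = []
    # candidate genes: spread over equal slots so they never overlap
    slot = (cand_end - cand_start) // max(config.n_candidate_genes, 1)
    for i in range(config.n_candidate_genes):
        g = _draw_gene(
            rng, cand_chrom, cand_start + i * slot, cand_start + (i + 1) * slot,
            f"cand{i}", ref[cand_chrom],
        )
        if g is not None:
            genes.append(g)
    for chrom in chroms:
        lo0 = 0
        span = lengths[chrom] // max(config.n_background_genes_per_chrom, 1)
        for i in range(config.n_background_genes_per_chrom):
            lo, hi = lo0 + i * span, lo0 + (i + 1) * span
            if chrom == cand_chrom and not (hi <= cand_start or lo >= cand_end):
                continue  # keep background genes out of the candidate region
            g = _draw_gene(rng, chrom, lo, hi, f"bg{i}", ref[chrom])
            if g is not None:
                genes.append(g)

    pop_ids = [f"{m}{i + 1}" for m in ("CP", "OP") for i in range(config.n_pops_per_mode)]
    pop_modes = [p[:2] for p in pop_ids]

    site_chrom, site_pos = [], []
    for chrom in chroms:
        n = rng.binomial(lengths[chrom], config.snp_density)
        pos = np.sort(rng.choice(lengths[chrom], size=n, replace=False))
        site_chrom.append(np.full(n, chrom, dtype=object))
        site_pos.append(pos)
    site_chrom = np.concatenate(site_chrom)
    site_pos = np.concatenate(site_pos)
    n_sites = site_pos.size

    is_candidate = (
        (site_chrom == cand_chrom) & (site_pos >= cand_start) & (site_pos < cand_end)
    )

    anc_idx = np.concatenate([ref[c][site_pos[site_chrom == c]] for c in chroms])
    # reorder to site order (sites were appended chromosome by chromosome)
    order = np.concatenate([np.flatnonzero(site_chrom == c) for c in chroms])
    anc_sorted = np.empty(n_sites, dtype=np.int8)
    anc_sorted[order] = anc_idx
    anc_base = BASES[anc_sorted]
    der_base = BASES[(anc_sorted + rng.integers(1, 4, size=n_sites)) % 4]
    _avoid_nonsense_alleles(
        genes, site_chrom, site_pos, anc_base, der_base, ref, rng
    )

    # mode-level frequencies
    mode_freq = np.zeros((n_sites, 2))  # columns CP, OP
    bg = ~is_candidate
    p0 = _neutral_sfs_freqs(rng, int(bg.sum()))
    if config.background_fst == 0.0:
        mode_freq[bg, 0] = mode_freq[bg, 1] = p0
    else:
        fstar = _beta_fst_param(config.background_fst)
        conc = (1.0 - fstar) / fstar
        for col in (0, 1):
            mode_freq[bg, col] = rng.beta(p0 * conc, (1.0 - p0) * conc)

    n_cand = int(is_candidate.sum())
    if n_cand:
        eps = _he_to_eps(config.candidate_he_op)
        if config.candidate_fst > 0:
            q = _candidate_cp_freq(config.candidate_fst, eps)
            q_site = np.clip(rng.normal(q, 0.03, size=n_cand), 0.02, 0.98)
        else:
            q_site = np.clip(rng.normal(0.5, 0.03, size=n_cand), 0.02, 0.98)
        flip = rng.random(n_cand) < 0.5  # which allele OP fixed for
        p_op = np.where(flip, eps, 1.0 - eps)
        p_cp = np.where(flip, 1.0 - q_site, q_site)
        mode_freq[is_candidate, 0] = p_cp
        mode_freq[is_candidate, 1] = p_op

    # population frequencies within modes
    pop_freqs = np.zeros((n_sites, len(pop_ids)))
    for j, mode in enumerate(pop_modes):
        col = 0 if mode == "CP" else 1
        if config.within_mode_fst == 0.0:
            pop_freqs[:, j] = mode_freq[:, col]
        else:
            fw = _beta_fst_param(config.within_mode_fst)
            conc = (1.0 - fw) / fw
            pm = np.clip(mode_freq[:, col], 1e-9, 1 - 1e-9)
            pop_freqs[:, j] = rng.beta(pm * conc, (1.0 - pm) * conc)

    return TruthState(
        config=config,
        chrom_lengths=lengths,
        ref_seqs=ref,
        site_chrom=site_chrom,
        site_pos=site_pos,
        anc_base=anc_base,
        der_base=der_base,
        is_candidate=is_candidate,
        pop_freqs=pop_freqs,
        pop_ids=pop_ids,
        pop_modes=pop_modes,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# Pool-seq sampling


def make_metadata(config: TruthConfig) -> PoolMetadata:
    rows = []
    for mode in ("CP", "OP"):
        for i in range(config.n_pops_per_mode):
            pop = f"{mode}{i + 1}"
            for rep in (1, 2):
                rows.append(
                    {
                        "library_id": f"{pop}_L{rep}",
                        "population_id": pop,
                        "mode": mode,
                        "n_lineages": config.lineages_per_pool[mode],
                    }
                )
    return PoolMetadata(pd.DataFrame(rows))


def _sample_counts_at_sites(
    truth: TruthState, config: TruthConfig, rng: np.random.Generator
):
    """Two-stage Pool-seq sampling at every truth site.

    Returns (counts, metadata): counts has shape (n_sites, n_libraries, 6).
    """
    meta = make_metadata(config)
    n_sites = truth.site_pos.size
    n_lib = len(meta)
    counts = np.zeros((n_sites, n_lib, 6), dtype=np.int64)
    anc_col = np.array([BASE_TO_COL[b] for b in truth.anc_base])
    der_col = np.array([BASE_TO_COL[b] for b in truth.der_base])
    for p_idx, pop in enumerate(meta.populations):
        two_l = meta.chromosomes_in_pool(pop)
        # one DNA pool per population, shared by its replicate libraries
        pool_freq = rng.binomial(two_l, truth.pop_freqs[:, p_idx]) / two_l
        for lib in meta.libraries_of(pop):
            depth = rng.poisson(config.mean_depth_per_library, size=n_sites)
            k_der = rng.binomial(depth, pool_freq)
            rows = np.arange(n_sites)
            counts[rows, lib, der_col] += k_der
            counts[rows, lib, anc_col] += depth - k_der
    return counts, meta


def sample_pools(
    truth: TruthState, config: TruthConfig, rng: np.random.Generator | None = None
) -> tuple[SyncData, PoolMetadata]:
    """Sample per-library read counts at all truth sites (SNP-only sync)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    counts, meta = _sample_counts_at_sites(truth, config, rng)
    return (
        SyncData(
            chrom=truth.site_chrom,
            pos=truth.site_pos,
            ref=truth.anc_base.astype(object),
            counts=counts,
            metadata=meta,
        ),
        meta,
    )


def sample_region_sync(
    truth: TruthState,
    config: TruthConfig,
    snp_sync: SyncData,
    rng: np.random.Generator | None = None,
) -> SyncData:
    """Full-coverage sync over the candidate interval.

    Monomorphic positions get fresh Poisson depths of pure reference
    reads; positions that are truth sites reuse the counts already drawn
    for the SNP sync, so the two files agree wherever they overlap.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    chrom, start, end = config.candidate_interval
    meta = snp_sync.metadata
    n_pos = end - start
    n_lib = len(meta)
    positions = np.arange(start, end)
    ref_idx = truth.ref_seqs[chrom][start:end]
    counts = np.zeros((n_pos, n_lib, 6), dtype=np.int64)
    depth = rng.poisson(config.mean_depth_per_library, size=(n_pos, n_lib))
    rows = np.repeat(np.arange(n_pos), n_lib)
    libs = np.tile(np.arange(n_lib), n_pos)
    sync_col = np.array([BASE_TO_COL[b] for b in BASES])  # BASES index -> sync column
    counts[rows, libs, np.repeat(sync_col[ref_idx], n_lib)] = depth.ravel()
    # overwrite truth sites with the already-sampled SNP counts
    in_region = (
        (snp_sync.chrom == chrom) & (snp_sync.pos >= start) & (snp_sync.pos < end)
    )
    counts[snp_sync.pos[in_region] - start] = snp_sync.counts[in_region]
    return SyncData(
        chrom=np.full(n_pos, chrom, dtype=object),
        pos=positions,
        ref=BASES[ref_idx].astype(object),
        counts=counts,
        metadata=meta,
    )


def write_outgroup(truth: TruthState, config: TruthConfig, path: str | Path) -> dict[str, str]:
    """Outgroup genome: the ancestral sequence with iid substitutions at
    rate ``outgroup_divergence`` (substituted base drawn uniformly from
    the three alternatives)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    seqs = {}
    for chrom, ref in truth.ref_seqs.items():
        out = ref.copy()
        hit = rng.random(out.size) < config.outgroup_divergence
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        seqs[chrom] = "".join(BASES[out])
    write_fasta(seqs, path)
    return seqs


def simulate_depth_tracks(
    n_positions: int,
    mean_depth: float,
    rng: np.random.Generator,
    copy_number: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson per-position depth tracks for the OP and CP mode pools.

    ``copy_number`` scales the OP and CP means, emulating segmental
    deletions/duplications (equal copy number -> expected normalized
    ratio 0.5).
    """
    op = rng.poisson(mean_depth * copy_number[0], size=n_positions)
    cp = rng.poisson(mean_depth * copy_number[1], size=n_positions)
    return op.astype(float), cp.astype(float)


def write_dataset(config: TruthConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write the full synthetic dataset to ``outdir``.

    Produces: snp.sync (truth sites genome-wide), region.sync (every
    position of the candidate interval), reference.fa, outgroup.fa,
    genes.gff3 and pools.tsv. Fully determined by ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_truth(config)
    snp_sync, meta = sample_pools(truth, config)
    region_sync = sample_region_sync(truth, config, snp_sync)
    paths = {
        "snp_sync": outdir / "snp.sync",
        "region_sync": outdir / "region.sync",
        "reference": outdir / "reference.fa",
        "outgroup": outdir / "outgroup.fa",
        "gff": outdir / "genes.gff3",
        "metadata": outdir / "pools.tsv",
    }
    write_sync(snp_sync.to_records(), paths["snp_sync"])
    write_sync(region_sync.to_records(), paths["region_sync"])
    write_fasta(truth.reference(), paths["reference"])
    write_outgroup(truth, config, paths["outgroup"])
    write_gff3(truth.genes, paths["gff"])
    meta.write(paths["metadata"])
    return paths
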