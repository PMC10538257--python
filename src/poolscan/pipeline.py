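"""Orchestration: simulate -> filter -> stats -> scan -> date -> annotate.

Each stage reads and writes plain files in the run directory so any
stage can be re-run in isolation; ``run_all`` chains them and writes a
manifest recording the resolved configuration, seeds and output
digests. Thresholds default to the values of the analysis the package
reimplements.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    divergence_dating as dd,
    genome_scan as gs,
    io_formats as io,
    popgen_estimators as pe,
    synthetic_data as sd,
    variant_effects as ve,
    variant_filters as vf,
)

logger = logging.getLogger("poolscan")

__all__ = ["RunConfig", "PipelineError", "run_all",
           "stage_simulate", "stage_filter", "stage_stats",
           "stage_scan", "stage_date", "stage_annotate"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Threshold defaults are the reimplemented analysis's stated values:
    MAC >= 4; per-population depth in [20, 60]; MAF >= 5%; 20-kb F_ST
    windows sliding by 5 kb; 100-kb diversity windows; uniform depth 30
    (max 360) for Tajima's D with min-count 2 and min covered fraction
    0.5; nolowfreq 3 for Fay & Wu's H; window F_ST threshold 0.25 and
    per-SNP association threshold 60 for region delimitation; 2-kb
    depth-ratio windows; F_ST > 0.5 and depth >= 20 for variant
    annotation; 100 consensus replicates; dS calibration 0.2268 <-> 22
    My.
    """

    outdir: str = "poolscan_run"
    seed: int = 0
    simulate: bool = True
    truth: sd.TruthConfig = dataclasses.field(default_factory=sd.TruthConfig)
    # external inputs (used when simulate=False; else filled by simulate)
    snp_sync: str | None = None
    region_sync: str | None = None
    reference: str | None = None
    outgroup: str | None = None
    gff: str | None = None
    metadata: str | None = None
    assoc_scores: str | None = None  # optional per-SNP association TSV
    extra_variants: str | None = None  # optional indel/variant TSV
    # variant calling / filtering
    mac_min: int = 4
    depth_min: int = 20
    depth_max: int = 60
    maf_min: float = 0.05
    # windowed statistics
    fst_window: int = 20_000
    fst_step: int = 5_000
    big_window: int = 100_000
    fst_estimator: str = "pool_corrected"
    target_coverage: int = 30
    max_coverage: int = 360
    min_count: int = 2
    min_covered_fraction: float = 0.5
    nolowfreq: int = 3
    compute_fwh: bool = True
    # region delimitation and structure scan
    fst_threshold: float = 0.25
    assoc_threshold: float = 60.0
    min_assoc: int = 1
    snp_trim_fst: float = 0.5
    depth_ratio_window: int = 2_000
    # dating
    replicates: int = 100
    mu_parth: float = 2.7e-10
    mu_parth_ci: tuple = (1.9e-10, 3.5e-10)
    mu_sex: float = 2.96e-9
    mu_sex_ci: tuple = (1.52e-9, 4.99e-9)
    n_gen: int = 15
    ds_cal: float = 0.2268
    t_cal: float = 22e6
    # annotation
    variant_fst_min: float = 0.5
    variant_depth_min: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        truth = sd.TruthConfig(**raw.pop("truth", {}))
        cfg = cls(truth=truth, **raw)
        cfg.truth.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def rates(self) -> dd.MutationRates:
        return dd.compose_mutation_rates(
            self.mu_parth, tuple(self.mu_parth_ci),
            self.mu_sex, tuple(self.mu_sex_ci), self.n_gen,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig, out: Path):
    meta = io.PoolMetadata.read(cfg.metadata or out / "pools.tsv")
    sync = io.load_sync(cfg.snp_sync or out / "snp.sync", meta)
    return meta, sync


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    cfg.truth.seed = cfg.seed
    paths = sd.write_dataset(cfg.truth, out)
    cfg.snp_sync = str(paths["snp_sync"])
    cfg.region_sync = str(paths["region_sync"])
    cfg.reference = str(paths["reference"])
    cfg.outgroup = str(paths["outgroup"])
    cfg.gff = str(paths["gff"])
    cfg.metadata = str(paths["metadata"])
    return paths


def stage_filter(cfg: RunConfig) -> dict[str, Path]:
    """SNP calling (nonfiltered) and depth/MAF filtering (filtered)."""
    out = Path(cfg.outdir)
    meta, sync = _load_inputs(cfg, out)
    pop_sync = io.merge_replicate_libraries(sync)
    nonfiltered = vf.call_snps(pop_sync, mac_min=cfg.mac_min)
    filtered = vf.filter_snps(
        nonfiltered, cfg.depth_min, cfg.depth_max, cfg.maf_min
    )
    paths = {
        "nonfiltered": out / "nonfiltered_snps.tsv",
        "filtered": out / "filtered_snps.tsv",
    }
    nonfiltered.to_frame().to_csv(paths["nonfiltered"], sep="\t", index=False)
    filtered.to_frame().to_csv(paths["filtered"], sep="\t", index=False)
    logger.info(
        "filter: %d nonfiltered SNPs, %d after depth/MAF filters",
        len(nonfiltered), len(filtered),
    )
    return paths


def _mode_counts(snps: vf.SnpTable):
    """Mode-level (minor counts, depths, pool sizes) from a population
    SnpTable; columns ordered (CP, OP)."""
    meta = snps.metadata
    pops = meta.populations
    cols = {m: [j for j, p in enumerate(pops) if meta.mode_of(p) == m] for m in io.MODES}
    minor = np.column_stack([snps.minor_counts[:, cols[m]].sum(axis=1) for m in io.MODES])
    depth = np.column_stack([snps.depth[:, cols[m]].sum(axis=1) for m in io.MODES])
    pool_sizes = tuple(
        sum(meta.chromosomes_in_pool(pops[j]) for j in cols[m]) for m in io.MODES
    )
    return minor, depth, pool_sizes


def _chrom_lengths(reference_path: str) -> dict[str, int]:
    return {c: len(s) for c, s in io.read_fasta(reference_path).items()}


def stage_stats(cfg: RunConfig) -> dict[str, Path]:
    """Per-SNP F_ST and the windowed statistics tracks."""
    out = Path(cfg.outdir)
    meta = io.PoolMetadata.read(cfg.metadata)
    filtered = vf.SnpTable.from_frame(
        pd.read_csv(out / "filtered_snps.tsv", sep="\t"), meta.population_level()
    )
    nonfiltered = vf.SnpTable.from_frame(
        pd.read_csv(out / "nonfiltered_snps.tsv", sep="\t"), meta.population_level()
    )
    lengths = _chrom_lengths(cfg.reference)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10]))

    # per-SNP F_ST between modes (filtered dataset)
    minor, depth, pools = _mode_counts(filtered)
    num, den = pe.fst_components(minor, depth, pools, cfg.fst_estimator)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    snp_fst = pd.DataFrame(
        {"chrom": filtered.chrom, "pos": filtered.pos, "fst": fst,
         "num": num, "den": den}
    )
    genomewide = pe.fst_multilocus(num, den)
    logger.info("stats: genome-wide multilocus F_ST = %.4f", genomewide)

    # sliding F_ST windows
    fst_rows = []
    for chrom, length in lengths.items():
        sel = snp_fst["chrom"] == chrom
        wins = gs.make_windows(length, cfg.fst_window, cfg.fst_step)
        wm = gs.window_means(
            snp_fst.loc[sel, "pos"].to_numpy(),
            snp_fst.loc[sel, "num"].to_numpy(),
            wins,
            weights=None,
        )
        # ratio-of-sums inside windows: mean(num)/mean(den)
        dm = gs.window_means(
            snp_fst.loc[sel, "pos"].to_numpy(),
            snp_fst.loc[sel, "den"].to_numpy(),
            wins,
        )
        wm["value"] = wm["value"] / dm["value"]
        wm.insert(0, "chrom", chrom)
        fst_rows.append(wm)
    fst_windows = pd.concat(fst_rows, ignore_index=True)

    # 100-kb windows: H_E, Tajima's D, Fay & Wu's H per mode
    nf_minor, nf_depth, _ = _mode_counts(nonfiltered)
    he = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        f_minor, f_depth, _ = _mode_counts(filtered)
        for j, mode in enumerate(io.MODES):
            he[mode] = pe.expected_heterozygosity(f_minor[:, j] / f_depth[:, j])
    sub = {}
    for j, mode in enumerate(io.MODES):
        sub[mode] = pe.subsample_to_uniform_depth(
            nf_minor[:, j], nf_depth[:, j],
            target=cfg.target_coverage, max_depth=cfg.max_coverage, rng=rng,
        )
    # outgroup polarization for FWH
    derived = {m: np.full(len(nonfiltered), -1, dtype=np.int64) for m in io.MODES}
    if cfg.compute_fwh:
        if not cfg.outgroup or not Path(cfg.outgroup).exists():
            raise PipelineError("stats: Fay & Wu's H requested but no outgroup FASTA")
        og = io.read_fasta(cfg.outgroup)
        n = cfg.target_coverage
        for i in range(len(nonfiltered)):
            base = og[str(nonfiltered.chrom[i])][int(nonfiltered.pos[i])]
            for mode in io.MODES:
                k = sub[mode][i]
                if k < 0:
                    continue
                pol = pe.polarize(
                    str(nonfiltered.major[i]), str(nonfiltered.minor[i]),
                    n - int(k), int(k), base,
                )
                if pol is not None:
                    derived[mode][i] = pol[1]

    big_rows = []
    for chrom, length in lengths.items():
        wins = gs.make_windows(length, cfg.big_window)
        selF = filtered.chrom == chrom
        selN = nonfiltered.chrom == chrom
        posF = filtered.pos[selF]
        posN = nonfiltered.pos[selN]
        for start, end in wins:
            row = {"chrom": chrom, "start": start, "end": end}
            inF = (posF >= start) & (posF < end)
            inN = (posN >= start) & (posN < end)
            row["n_snps"] = int(inN.sum())
            for mode in io.MODES:
                hv = he[mode][selF][inF]
                hv = hv[np.isfinite(hv)]
                row[f"he_{mode.lower()}"] = float(hv.mean()) if hv.size else np.nan
                kw = sub[mode][selN][inN]
                kw = kw[kw >= 0]
                row[f"tajimas_d_{mode.lower()}"] = pe.tajimas_d(
                    kw, cfg.target_coverage, cfg.min_count,
                    covered_fraction=1.0,
                    min_covered_fraction=cfg.min_covered_fraction,
                )
                if cfg.compute_fwh:
                    kd = derived[mode][selN][inN]
                    kd = kd[kd >= 0]
                    row[f"fwh_{mode.lower()}"] = pe.fay_wu_h(
                        kd, cfg.target_coverage, cfg.nolowfreq
                    )
            big_rows.append(row)
    big_windows = pd.DataFrame(big_rows)

    paths = {
        "snp_fst": out / "snp_fst.tsv",
        "fst_windows": out / "fst_windows.tsv",
        "big_windows": out / "windows_100kb.tsv",
        "summary": out / "stats_summary.json",
    }
    snp_fst.to_csv(paths["snp_fst"], sep="\t", index=False)
    fst_windows.to_csv(paths["fst_windows"], sep="\t", index=False)
    big_windows.to_csv(paths["big_windows"], sep="\t", index=False)
    with open(paths["summary"], "w") as fh:
        json.dump({"genomewide_fst": genomewide}, fh, indent=1)
    return paths


def stage_scan(cfg: RunConfig) -> dict[str, Path]:
    """Candidate-region delimitation, depth-ratio scan and comparisons."""
    out = Path(cfg.outdir)
    fst_windows = pd.read_csv(out / "fst_windows.tsv", sep="\t")
    snp_fst = pd.read_csv(out / "snp_fst.tsv", sep="\t")
    assoc = (
        pd.read_csv(cfg.assoc_scores, sep="\t") if cfg.assoc_scores else None
    )
    regions = gs.delimit_candidate_region(
        fst_windows, snp_fst, assoc,
        fst_threshold=cfg.fst_threshold,
        assoc_threshold=cfg.assoc_threshold,
        min_assoc=cfg.min_assoc,
        snp_trim_fst=cfg.snp_trim_fst,
    )
    if regions:
        main = max(regions, key=lambda r: r.mean_fst * r.length)
        logger.info(
            "scan: main candidate region %s:%d-%d (%.0f kb, mean F_ST %.3f)",
            main.chrom, main.start, main.end, main.length / 1000, main.mean_fst,
        )
    else:
        main = None
        logger.warning("scan: no window exceeded the F_ST threshold")

    paths = {
        "bed": out / "candidate_regions.bed",
        "regions": out / "candidate_regions.tsv",
        "comparisons": out / "comparisons.json",
    }
    with open(paths["bed"], "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tfst={r.mean_fst:.4f}\n")
    pd.DataFrame([dataclasses.asdict(r) for r in regions]).to_csv(
        paths["regions"], sep="\t", index=False
    )

    comparisons: dict = {}
    big = pd.read_csv(out / "windows_100kb.tsv", sep="\t")
    if main is not None:
        inside = (
            (big["chrom"] == main.chrom)
            & (big["start"] < main.end)
            & (big["end"] > main.start)
        )
        for col in [c for c in big.columns if c.startswith(("he_", "tajimas_d_", "fwh_"))]:
            comparisons[f"{col}_candidate_vs_rest"] = gs.compare_candidate_vs_rest(
                big.loc[inside, col], big.loc[~inside, col]
            )
    for stat in ("he", "tajimas_d", "fwh"):
        op, cp = f"{stat}_op", f"{stat}_cp"
        if op in big.columns and cp in big.columns:
            comparisons[f"{stat}_op_vs_cp"] = gs.compare_modes_paired(big[op], big[cp])

    # depth-ratio structure scan over the region sync, per mode
    if cfg.region_sync and Path(cfg.region_sync).exists():
        meta = io.PoolMetadata.read(cfg.metadata)
        region = io.load_sync(cfg.region_sync, meta)
        mode_sync = io.pool_by_mode(io.merge_replicate_libraries(region))
        depth = mode_sync.depth()
        modes = mode_sync.metadata.populations
        d_op = depth[:, modes.index("OP")].astype(float)
        d_cp = depth[:, modes.index("CP")].astype(float)
        ratio = gs.depth_ratio_scan(
            d_op, d_cp, window=cfg.depth_ratio_window, start=int(region.pos.min())
        )
        ratio.insert(0, "chrom", region.chrom[0])
        paths["depth_ratio"] = out / "depth_ratio.tsv"
        ratio.to_csv(paths["depth_ratio"], sep="\t", index=False)

    with open(paths["comparisons"], "w") as fh:
        json.dump(comparisons, fh, indent=1)
    return paths


def _region_inputs(cfg: RunConfig, out: Path):
    """Shared preparation for dating/annotation: the main region, its
    callable mask, mode frequencies and gene models."""
    regions = pd.read_csv(out / "candidate_regions.tsv", sep="\t")
    if regions.empty:
        raise PipelineError("date: no candidate region delimited by the scan")
    row = regions.loc[(regions["mean_fst"] * (regions["end"] - regions["start"])).idxmax()]
    region = gs.CandidateRegion(
        chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
        mean_fst=float(row["mean_fst"]),
    )
    meta = io.PoolMetadata.read(cfg.metadata)
    sync = io.load_sync(cfg.region_sync, meta)
    sync = sync.restrict(region.chrom, region.start, region.end)
    if len(sync) < region.length:
        raise PipelineError(
            "date: region sync does not cover the candidate region"
        )
    pop_sync = io.merge_replicate_libraries(sync)
    depth = pop_sync.depth()
    callable_mask = (depth >= cfg.depth_min).all(axis=1)
    nonfiltered = vf.SnpTable.from_frame(
        pd.read_csv(out / "nonfiltered_snps.tsv", sep="\t"), meta.population_level()
    )
    in_region = (
        (nonfiltered.chrom == region.chrom)
        & (nonfiltered.pos >= region.start)
        & (nonfiltered.pos < region.end)
    )
    snps = nonfiltered.subset(in_region)
    return region, meta, pop_sync, callable_mask, snps


def stage_date(cfg: RunConfig) -> dict[str, Path]:
    """The three divergence-time estimates for the delimited region."""
    out = Path(cfg.outdir)
    region, meta, pop_sync, callable_mask, snps = _region_inputs(cfg, out)
    rates = cfg.rates()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 20]))

    offsets = snps.pos - region.start
    snp_callable = callable_mask[offsets]
    n_sites = int(callable_mask.sum())

    minor, depth, _ = _mode_counts(snps)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cp = minor[:, 0] / depth[:, 0]
        p_op = minor[:, 1] / depth[:, 1]
    usable = snp_callable & np.isfinite(p_cp) & np.isfinite(p_op)

    # approach 1: net divergence over all callable sites
    full_op = np.zeros(n_sites)
    full_cp = np.zeros(n_sites)
    idx_callable = np.cumsum(callable_mask) - 1  # offset -> callable index
    full_op[idx_callable[offsets[usable]]] = p_op[usable]
    full_cp[idx_callable[offsets[usable]]] = p_cp[usable]
    da = dd.net_divergence_da(full_op, full_cp)
    est_da = dd.time_from_da(da, rates)

    # approach 2: consensus substitution counts
    ref = io.read_fasta(cfg.reference)[region.chrom][region.start : region.end]
    # put the global major allele on the backbone, then draw the minor
    backbone = np.frombuffer(ref.encode(), dtype="S1").copy()
    backbone[offsets[usable]] = np.asarray(
        snps.major[usable], dtype="S1"
    )
    backbone_seq = backbone.tobytes().decode()
    genes = [
        g for g in io.read_gff_cds(cfg.gff)
        if g.chrom == region.chrom and g.span[0] >= region.start and g.span[1] <= region.end
    ]
    counts = []
    ds_reps = []
    first_pair = None
    for rep in range(cfg.replicates):
        pair = dd.draw_consensus(
            p_op[usable], p_cp[usable], backbone_seq,
            offsets[usable], np.asarray(snps.minor[usable], dtype=object),
            callable_mask, rng, seed=rep,
        )
        if first_pair is None:
            first_pair = pair
        counts.append(dd.count_substitutions(pair))
        if genes:
            try:
                med, _ = dd.pairwise_ds(pair, genes, region.start)
                ds_reps.append(med)
            except ValueError:
                pass
    est_counts = dd.time_from_counts(np.array(counts), n_sites, rates)

    results = {
        "region": dataclasses.asdict(region),
        "n_sites_callable": n_sites,
        "rates": dataclasses.asdict(rates),
        "estimates": [dataclasses.asdict(est_da), dataclasses.asdict(est_counts)],
    }
    paths = {"dating": out / "dating.json", "consensus": out / "consensus.fa"}
    if ds_reps:
        ds_arr = np.array(ds_reps)
        ds_point = float(ds_arr.mean())
        ds_ci = tuple(float(x) for x in np.percentile(ds_arr, [2.5, 97.5]))
        est_ds = dd.time_from_ds(ds_point, cfg.ds_cal, cfg.t_cal, ds_ci)
        results["estimates"].append(dataclasses.asdict(est_ds))
        _, per_gene = dd.pairwise_ds(first_pair, genes, region.start)
        pd.DataFrame(
            sorted(per_gene.items()), columns=["gene_id", "ds"]
        ).to_csv(out / "per_gene_ds.tsv", sep="\t", index=False)
        paths["per_gene_ds"] = out / "per_gene_ds.tsv"
    io.write_fasta(
        {"op_consensus": first_pair.op_seq, "cp_consensus": first_pair.cp_seq},
        paths["consensus"],
    )
    with open(paths["dating"], "w") as fh:
        json.dump(results, fh, indent=1, default=list)
    for est in results["estimates"]:
        logger.info(
            "date: %s -> %.0f years (95%% CI %.0f-%.0f)",
            est["method"], est["t_years"], est["ci95"][0], est["ci95"][1],
        )
    return paths


def stage_annotate(cfg: RunConfig) -> dict[str, Path]:
    """Classify high-F_ST variants in the region; per-gene summary."""
    out = Path(cfg.outdir)
    region, meta, pop_sync, callable_mask, snps = _region_inputs(cfg, out)
    reference = io.read_fasta(cfg.reference)
    genes = [g for g in io.read_gff_cds(cfg.gff) if g.chrom == region.chrom]

    minor, depth_mode, pools = _mode_counts(snps)
    num, den = pe.fst_components(minor, depth_mode, pools, cfg.fst_estimator)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
        p_cp = minor[:, 0] / depth_mode[:, 0]
        p_op = minor[:, 1] / depth_mode[:, 1]

    variants: list[ve.Variant] = []
    for i in range(len(snps)):
        ref_base = reference[region.chrom][int(snps.pos[i])]
        alleles = {str(snps.major[i]), str(snps.minor[i])}
        alts = alleles - {ref_base}
        if len(alts) != 1:
            continue  # reference matches neither allele
        variants.append(
            ve.Variant(
                chrom=region.chrom, pos=int(snps.pos[i]), ref=ref_base,
                alt=alts.pop(), fst=float(fst[i]), depths=snps.depth[i],
                freq_op=float(p_op[i]), freq_cp=float(p_cp[i]),
            )
        )
    if cfg.extra_variants:
        extra = pd.read_csv(cfg.extra_variants, sep="\t")
        for _, r in extra.iterrows():
            variants.append(
                ve.Variant(
                    chrom=str(r["chrom"]), pos=int(r["pos"]) - 1, ref=str(r["ref"]),
                    alt=str(r["alt"]), fst=float(r.get("fst", np.nan)),
                    depths=np.full(len(meta.populations), int(r.get("depth", 0))),
                )
            )
    selected = ve.select_candidate_variants(
        variants, cfg.variant_fst_min, cfg.variant_depth_min
    )
    calls = ve.classify_variants(selected, genes, reference)

    pop_meta = pop_sync.metadata
    modes = [pop_meta.mode_of(p) for p in pop_meta.populations]
    summary = ve.per_gene_summary(
        calls, genes,
        depth_by_pop=pop_sync.depth(),
        depth_positions=pop_sync.pos,
        pop_modes=modes,
        depth_min=cfg.variant_depth_min,
    )
    var_df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in selected],
            "pos": [v.pos + 1 for v in selected],
            "ref": [v.ref for v in selected],
            "alt": [v.alt for v in selected],
            "freq_op": [v.freq_op for v in selected],
            "freq_cp": [v.freq_cp for v in selected],
            "fst": [v.fst for v in selected],
            "gene_id": [c.gene_id for c in calls],
            "effect": [c.effect for c in calls],
            "impact": [c.impact for c in calls],
            "aa_change": [c.aa_change for c in calls],
        }
    )
    paths = {
        "variants": out / "candidate_variants.tsv",
        "gene_summary": out / "gene_summary.tsv",
    }
    var_df.to_csv(paths["variants"], sep="\t", index=False)
    summary.to_csv(paths["gene_summary"], sep="\t", index=False)
    logger.info(
        "annotate: %d candidate variants, %d with coding effects",
        len(selected),
        sum(1 for c in calls if c.impact in ("high", "moderate", "low")),
    )
    return paths


STAGES = [
    ("simulate", stage_simulate),
    ("filter", stage_filter),
    ("stats", stage_stats),
    ("scan", stage_scan),
    ("date", stage_date),
    ("annotate", stage_annotate),
]


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in order; returns the manifest (also written to
    ``outdir/manifest.json``)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    for name, fn in STAGES:
        if name == "simulate" and not cfg.simulate:
            continue
        t0 = time.monotonic()
        try:
            paths = fn(cfg)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        dt = time.monotonic() - t0
        logger.info("stage %s done in %.1f s", name, dt)
        manifest["stages"][name] = {"seconds": round(dt, 3)}
        for key, p in paths.items():
            manifest["outputs"][f"{name}/{key}"] = {
                "path": str(p), "sha256": _sha256(Path(p))
            }
    manifest["config"] = cfg.to_dict()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
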