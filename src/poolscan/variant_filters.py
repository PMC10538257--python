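"""SNP identification and the two-stage filtering producing the
"nonfiltered" (MAC-based) and "filtered" (depth + MAF) SNP datasets.

A SNP is called where at least two nucleotides are observed across all
populations and the global minor allele is supported by at least
``mac_min`` reads. Triallelic positions are tolerated only when the
third allele carries a single read (that allele is ignored and the site
treated as biallelic); with two or more extra reads the site is dropped.
The second stage keeps SNPs whose per-population depth lies in
[depth_min, depth_max] (bounds inclusive) with global minor-allele
frequency >= maf_min.

Depth counts A/T/C/G reads only; N and deletion columns never enter
allele counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import NUC_COLS, SYNC_ALLELES, PoolMetadata, SyncData

__all__ = ["SnpTable", "call_snps", "filter_snps"]


@dataclasses.dataclass
class SnpTable:
    """Biallelic SNPs with per-population major/minor counts.

    "major"/"minor" refer to the two retained alleles ranked by global
    count; per-population depth is major + minor only.
    """

    chrom: np.ndarray
    pos: np.ndarray  # 0-based
    ref: np.ndarray
    major: np.ndarray  # allele characters
    minor: np.ndarray
    major_counts: np.ndarray  # (n_snps, n_pops)
    minor_counts: np.ndarray
    metadata: PoolMetadata

    def __len__(self) -> int:
        return self.pos.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.major_counts + self.minor_counts

    @property
    def maf(self) -> np.ndarray:
        """Global minor-allele frequency (counts summed over populations)."""
        mi = self.minor_counts.sum(axis=1)
        ma = self.major_counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return mi / (mi + ma)

    def subset(self, mask: np.ndarray) -> "SnpTable":
        return SnpTable(
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.major[mask],
            self.minor[mask],
            self.major_counts[mask],
            self.minor_counts[mask],
            self.metadata,
        )

    def minor_frequencies(self) -> np.ndarray:
        """(n_snps, n_pops) per-population minor-allele frequency."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.minor_counts / self.depth

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos + 1,  # 1-based in files
                "ref": self.ref,
                "major": self.major,
                "minor": self.minor,
                "maf": self.maf,
            }
        )
        for j, pop in enumerate(self.metadata.populations):
            df[f"{pop}_major"] = self.major_counts[:, j]
            df[f"{pop}_minor"] = self.minor_counts[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: PoolMetadata) -> "SnpTable":
        pops = metadata.populations
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64) - 1,
            ref=df["ref"].to_numpy(dtype=object),
            major=df["major"].to_numpy(dtype=object),
            minor=df["minor"].to_numpy(dtype=object),
            major_counts=df[[f"{p}_major" for p in pops]].to_numpy(dtype=np.int64),
            minor_counts=df[[f"{p}_minor" for p in pops]].to_numpy(dtype=np.int64),
            metadata=metadata,
        )


def call_snps(sync: SyncData, mac_min: int = 4) -> SnpTable:
    """Identify biallelic SNPs from population-level counts.

    ``sync`` must already be summed to population level (see
    :func:`poolscan.io_formats.merge_replicate_libraries`).
    """
    nuc = sync.counts[:, :, NUC_COLS]  # (sites, pops, 4)
    glob = nuc.sum(axis=1)  # (sites, 4)
    # rank alleles by global count; top two are the candidate pair
    order = np.argsort(glob, axis=1)[:, ::-1]
    top2 = np.take_along_axis(glob, order[:, :2], axis=1)
    extra = glob.sum(axis=1) - top2.sum(axis=1)
    keep = (
        (top2[:, 1] >= mac_min)  # MAC on the global minor allele
        & (extra <= 1)  # a lone third-allele read is ignored, >=2 drops the site
    )
    idx = np.flatnonzero(keep)
    maj_allele = order[idx, 0]
    min_allele = order[idx, 1]
    alleles = np.array(SYNC_ALLELES[:4])
    pop_nuc = nuc[idx]  # (n, pops, 4)
    major_counts = np.take_along_axis(
        pop_nuc, maj_allele[:, None, None].repeat(pop_nuc.shape[1], axis=1), axis=2
    )[:, :, 0]
    minor_counts = np.take_along_axis(
        pop_nuc, min_allele[:, None, None].repeat(pop_nuc.shape[1], axis=1), axis=2
    )[:, :, 0]
    return SnpTable(
        chrom=sync.chrom[idx],
        pos=sync.pos[idx],
        ref=sync.ref[idx],
        major=alleles[maj_allele],
        minor=alleles[min_allele],
        major_counts=major_counts,
        minor_counts=minor_counts,
        metadata=sync.metadata,
    )


def filter_snps(
    snps: SnpTable,
    depth_min: int = 20,
    depth_max: int = 60,
    maf_min: float = 0.05,
) -> SnpTable:
    """Depth-range and MAF filter producing the "filtered" dataset.

    Keeps SNPs where every population's depth lies in
    [depth_min, depth_max] and the global MAF is at least ``maf_min``
    (all bounds inclusive).
    """
    depth = snps.depth
    ok = (depth >= depth_min).all(axis=1) & (depth <= depth_max).all(axis=1)
    ok &= snps.maf >= maf_min
    return snps.subset(ok)
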