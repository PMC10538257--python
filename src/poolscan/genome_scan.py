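"""Window construction, candidate-region delimitation, the depth-ratio
structural scan, and candidate-vs-rest comparisons.

The delimitation rule codifies a call the original analysis made by
eye: take maximal runs of overlapping sliding windows whose mean F_ST
meets a threshold, optionally require corroborating per-SNP association
scores (e.g. an externally computed C2 statistic), and trim each run to
the outermost strongly differentiated SNPs (per-SNP F_ST > 0.5).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WindowStat",
    "CandidateRegion",
    "make_windows",
    "window_means",
    "delimit_candidate_region",
    "depth_ratio_scan",
    "compare_candidate_vs_rest",
    "compare_modes_paired",
]


@dataclasses.dataclass
class CandidateRegion:
    """A delimited high-differentiation region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_fst: float
    n_high_assoc: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


#: alias kept for symmetry with the window TSV outputs
WindowStat = pd.DataFrame


def make_windows(chrom_length: int, size: int, step: int | None = None) -> np.ndarray:
    """Window intervals [0, size), [step, step+size), ... fully inside the
    chromosome; ``step=None`` gives nonoverlapping windows."""
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    starts = np.arange(0, chrom_length - size + 1, step, dtype=np.int64)
    return np.column_stack([starts, starts + size])


def window_means(
    pos: np.ndarray,
    values: np.ndarray,
    windows: np.ndarray,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean of a per-SNP statistic within each window.

    With ``weights`` (e.g. F_ST denominators) the mean is a
    ratio-of-sums; otherwise a plain average. NaN values are ignored.
    Returns columns start, end, n_snps, value.
    """
    pos = np.asarray(pos)
    values = np.asarray(values, dtype=float)
    out = []
    for start, end in windows:
        sel = (pos >= start) & (pos < end)
        v = values[sel]
        ok = np.isfinite(v)
        n = int(sel.sum())
        if not ok.any():
            out.append((start, end, n, np.nan))
            continue
        if weights is not None:
            w = np.asarray(weights, dtype=float)[sel][ok]
            tot = w.sum()
            mean = np.nan if tot <= 0 else float((v[ok] * w).sum() / tot)
        else:
            mean = float(v[ok].mean())
        out.append((start, end, n, mean))
    return pd.DataFrame(out, columns=["start", "end", "n_snps", "value"])


def _merge_runs(intervals: np.ndarray) -> list[tuple[int, int]]:
    """Union of sorted, possibly overlapping windows into maximal runs."""
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def delimit_candidate_region(
    fst_windows: pd.DataFrame,
    snp_fst: pd.DataFrame | None = None,
    assoc_scores: pd.DataFrame | None = None,
    fst_threshold: float = 0.25,
    assoc_threshold: float = 60.0,
    min_assoc: int = 1,
    snp_trim_fst: float = 0.5,
) -> list[CandidateRegion]:
    """Delimit candidate regions from windowed F_ST.

    ``fst_windows`` needs columns chrom, start, end, value. Optional
    ``snp_fst`` (chrom, pos, fst; pos 0-based) trims each run to the
    outermost SNP with F_ST > ``snp_trim_fst`` and provides the
    recomputed region mean. Optional ``assoc_scores`` (chrom, pos,
    score) confirms a run only when it contains >= ``min_assoc`` SNPs
    scoring above ``assoc_threshold``. Returns an empty list (not an
    error) when nothing exceeds the threshold.
    """
    regions: list[CandidateRegion] = []
    wins = fst_windows.dropna(subset=["value"])
    wins = wins[wins["value"] >= fst_threshold]
    for chrom, sub in wins.groupby("chrom", sort=True):
        iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
        iv = iv[np.argsort(iv[:, 0])]
        for start, end in _merge_runs(iv):
            if assoc_scores is not None:
                a = assoc_scores
                inside = (
                    (a["chrom"] == chrom) & (a["pos"] >= start) & (a["pos"] < end)
                )
                n_high = int((a.loc[inside, "score"] > assoc_threshold).sum())
                if n_high < min_assoc:
                    continue
            else:
                n_high = 0
            mean_fst = float(
                sub[(sub["start"] >= start) & (sub["end"] <= end)]["value"].mean()
            )
            if snp_fst is not None:
                s = snp_fst
                hit = (
                    (s["chrom"] == chrom)
                    & (s["pos"] >= start)
                    & (s["pos"] < end)
                    & (s["fst"] > snp_trim_fst)
                )
                if hit.any():
                    pos_hit = s.loc[hit, "pos"]
                    start, end = int(pos_hit.min()), int(pos_hit.max()) + 1
                member = (
                    (s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] < end)
                )
                fvals = s.loc[member, "fst"].dropna()
                if len(fvals):
                    mean_fst = float(fvals.mean())
            regions.append(
                CandidateRegion(
                    chrom=str(chrom), start=int(start), end=int(end),
                    mean_fst=mean_fst, n_high_assoc=n_high,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def depth_ratio_scan(
    depth_op: np.ndarray,
    depth_cp: np.ndarray,
    window: int = 2000,
    start: int = 0,
) -> pd.DataFrame:
    """Normalized OP/(OP+CP) depth ratio averaged in nonoverlapping windows.

    Each mode's per-position depth is first divided by that mode's mean
    over the scanned positions, so equal copy number gives an expected
    ratio of 0.5; a heterozygous-equivalent OP deletion halves the OP
    term and drives the expectation toward 1/3. Positions where both
    normalized depths are zero are ignored.
    """
    op = np.asarray(depth_op, dtype=float)
    cp = np.asarray(depth_cp, dtype=float)
    if op.shape != cp.shape:
        raise ValueError("depth tracks differ in length")
    mo, mc = op.mean(), cp.mean()
    if mo <= 0 or mc <= 0:
        raise ValueError("a mode has zero mean depth; nothing to normalize")
    opn, cpn = op / mo, cp / mc
    tot = opn + cpn
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot > 0, opn / tot, np.nan)
    n = op.size
    rows = []
    for w0 in range(0, n - window + 1, window):
        r = ratio[w0 : w0 + window]
        ok = np.isfinite(r)
        rows.append(
            (start + w0, start + w0 + window, int(ok.sum()),
             float(r[ok].mean()) if ok.any() else np.nan)
        )
    return pd.DataFrame(rows, columns=["start", "end", "n_positions", "value"])


def _ranksum(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return res, x, y


def compare_candidate_vs_rest(values_in, values_out) -> dict:
    """Two-sided Mann-Whitney comparison of window values inside vs
    outside the candidate region (exact for small untied samples)."""
    res, x, y = _ranksum(values_in, values_out)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_candidate": float(np.median(x)),
        "median_rest": float(np.median(y)),
        "n_candidate": len(x),
        "n_rest": len(y),
    }


def compare_modes_paired(values_op, values_cp) -> dict:
    """Two-sided Wilcoxon signed-rank comparison of paired window values
    (the same windows measured in the OP and CP pools)."""
    x = np.asarray(values_op, dtype=float)
    y = np.asarray(values_cp, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.all(x == y):
        return {"W": 0.0, "p_value": 1.0, "median_op": float(np.median(x)),
                "median_cp": float(np.median(y)), "n": len(x)}
    res = stats.wilcoxon(x, y, alternative="two-sided")
    return {
        "W": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_op": float(np.median(x)),
        "median_cp": float(np.median(y)),
        "n": len(x),
    }
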