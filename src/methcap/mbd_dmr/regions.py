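"""Region assembly from tested windows: merging, Simes, FDR, direction."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def simes_pvalue(pvalues: Sequence[float]) -> float:
    """Simes combined p-value: min over i of m * p_(i) / i, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("simes_pvalue requires a nonempty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    p_sorted = np.sort(p)
    combined = (m * p_sorted / np.arange(1, m + 1)).min()
    return float(min(combined, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def merge_windows(results: pd.DataFrame, max_gap: int = 50) -> List[np.ndarray]:
    """Group tested windows into regions.

    Windows on the same chromosome separated by no more than ``max_gap``
    bases (gap = next.start - current.end; overlapping windows have
    gap <= 0) are merged transitively. ``results`` must be sorted by
    (chrom, start). Returns one index array per region, referring to rows
    of ``results``.
    """
    chroms = results["chrom"].to_numpy()
    starts = results["start"].to_numpy()
    ends = results["end"].to_numpy()
    n = len(results)
    if n == 0:
        return []
    order_ok = True
    for i in range(1, n):
        if chroms[i] == chroms[i - 1] and starts[i] < starts[i - 1]:
            order_ok = False
            break
    if not order_ok:
        raise ValueError("window results must be sorted by (chrom, start)")

    regions: List[np.ndarray] = []
    members = [0]
    hull_end = ends[0]
    for i in range(1, n):
        same = chroms[i] == chroms[i - 1]
        if same and starts[i] - hull_end <= max_gap:
            members.append(i)
            hull_end = max(hull_end, ends[i])
        else:
            regions.append(np.asarray(members, dtype=np.int64))
            members = [i]
            hull_end = ends[i]
    regions.append(np.asarray(members, dtype=np.int64))
    return regions


def classify_direction(logfc: Sequence[float], pvalues: Sequence[float]) -> str:
    """Direction of the methylation change in the majority of member windows.

    Ties (counting exact-zero logFCs toward neither side) resolve to the
    direction of the smallest-p member window; a zero logFC there resolves
    to 'hyper' (deterministic convention).
    """
    logfc = np.asarray(list(logfc), dtype=float)
    pvalues = np.asarray(list(pvalues), dtype=float)
    if logfc.size == 0:
        raise ValueError("region must have >= 1 member window")
    n_pos = int(np.sum(logfc > 0))
    n_neg = int(np.sum(logfc < 0))
    if n_pos > n_neg:
        return "hyper"
    if n_neg > n_pos:
        return "hypo"
    best = int(np.argmin(pvalues))
    if logfc[best] < 0:
        return "hypo"
    return "hyper"


def build_regions(
    results: pd.DataFrame,
    max_gap: int = 50,
    fdr_cutoff: float = 0.05,
    counts: Optional[np.ndarray] = None,
    group_mask_a: Optional[np.ndarray] = None,
    group_mask_b: Optional[np.ndarray] = None,
    eff_lib_sizes: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assemble the region table from per-window test results.

    Returns one row per region: span (union hull of member windows), member
    count, Simes combined p, BH-adjusted FDR, direction, aggregate logFC,
    and a significance flag. The aggregate logFC pools member-window counts
    per contrast group (overlapping windows weight both groups identically,
    so the ratio stays unbiased); when count data are not supplied it falls
    back to the smallest-p member window's logFC.
    """
    member_lists = merge_windows(results, max_gap=max_gap)
    pooled = (
        counts is not None
        and group_mask_a is not None
        and group_mask_b is not None
        and eff_lib_sizes is not None
    )
    rows = []
    for members in member_lists:
        sub = results.iloc[members]
        p = sub["pvalue"].to_numpy()
        lfc = sub["logFC"].to_numpy()
        best = int(np.argmin(p))
        if pooled:
            block = counts[members]
            tot_a = float(block[:, group_mask_a].sum())
            tot_b = float(block[:, group_mask_b].sum())
            off_a = float(eff_lib_sizes[group_mask_a].sum()) * len(members)
            off_b = float(eff_lib_sizes[group_mask_b].sum()) * len(members)
            rate_a = (tot_a if tot_a > 0 else 0.5) / off_a
            rate_b = (tot_b if tot_b > 0 else 0.5) / off_b
            agg_lfc = float(np.log2(rate_a / rate_b))
        else:
            agg_lfc = float(lfc[best])
        rows.append(
            {
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "n_windows": len(members),
                "simes_p": simes_pvalue(p),
                "logFC": agg_lfc,
                "direction": classify_direction(lfc, p),
            }
        )
    regions = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_windows", "simes_p", "logFC", "direction"],
    )
    if len(regions):
        regions["fdr"] = bh_adjust(regions["simes_p"].to_numpy())
        # a zero FDR budget permits no discoveries, even at p == 0
        if fdr_cutoff > 0:
            regions["significant"] = regions["fdr"] <= fdr_cutoff
        else:
            regions["significant"] = False
    else:
        regions["fdr"] = np.empty(0)
        regions["significant"] = np.empty(0, dtype=bool)
    regions.attrs["members"] = member_lists
    return regions
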