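"""Trimmed-mean-of-M-values (TMM) normalization on background bins.

Enrichment coverage is compositionally biased: samples with more captured
signal spend a larger share of their reads on enriched regions. Factors are
therefore estimated from large background bins (default 10 kb), where most
counts reflect non-differential material, and rescaled to geometric mean 1.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from methcap.mbd_dmr.counting import WindowCountMatrix, count_windows
from methcap.simdata.capture import FragmentSet


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Two-sample TMM log2 factor (observation vs reference)."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if len(obs) == 0:
        return 0.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M, used as inverse weight
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.allclose(m, m[0], atol=1e-10):
        return float(m[0])  # degenerate: all ratios equal
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = m.argsort().argsort() + 1
    rank_a = a.argsort().argsort() + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_factors(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """TMM factors for a bins x samples count array, geometric mean 1."""
    counts = np.asarray(counts)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires >= 2 samples")
    if np.any(lib_sizes <= 0):
        bad = int(np.flatnonzero(lib_sizes <= 0)[0])
        raise ValueError(f"sample index {bad} has zero total counts")
    # reference: sample whose 75th count percentile (library-scaled) is
    # closest to the mean across samples
    f75 = np.array(
        [np.quantile(counts[:, j] / lib_sizes[j], 0.75) for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref], lib_sizes[j], lib_sizes[ref])
            if j != ref
            else 0.0
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0 ** (log_factors - log_factors.mean())
    return factors


def estimate_normalization(
    matrix: WindowCountMatrix,
    bin_width: int = 10_000,
    fragment_sets: Optional[Sequence[FragmentSet]] = None,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> np.ndarray:
    """TMM factors for the samples of ``matrix``.

    When ``fragment_sets`` and ``chrom_sizes`` are given, background bins of
    ``bin_width`` are counted from scratch (non-overlapping tiling); this is
    the intended composition-robust route. Otherwise window counts are
    pooled into bins by window start as an approximation.
    """
    if matrix.n_samples < 2:
        raise ValueError("normalization requires >= 2 samples")
    if np.any(matrix.lib_sizes <= 0):
        bad = matrix.samples["sample"].iloc[int(np.argmin(matrix.lib_sizes))]
        raise ValueError(f"sample {bad!r} has zero total counts")

    if fragment_sets is not None and chrom_sizes is not None:
        bins = count_windows(
            fragment_sets,
            chrom_sizes,
            width=bin_width,
            step=bin_width,
            fragment_extension=None,
        )
        bin_counts = bins.counts
    else:
        key = (
            matrix.windows["chrom"].astype(str)
            + ":"
            + (matrix.windows["start"] // bin_width).astype(str)
        )
        # windows overlap; pooled counts approximate bin totals up to a
        # constant factor, which cancels in the ratio-based statistic
        import pandas as pd

        bin_counts = (
            pd.DataFrame(matrix.counts).groupby(key.to_numpy()).sum().to_numpy()
        )
    return tmm_factors(bin_counts, matrix.lib_sizes)
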