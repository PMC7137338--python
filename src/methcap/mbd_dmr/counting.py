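"""Fragment counting in sliding windows and abundance filtering."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from methcap.simdata.capture import FragmentSet


@dataclass
class WindowCountMatrix:
    """Windows x samples fragment-overlap counts.

    ``windows`` holds chrom/start/end sorted by (chrom, start); ``counts``
    is aligned row-wise. ``lib_sizes`` are raw per-sample fragment totals;
    ``norm_factors`` (geometric mean 1) rescale them to effective library
    sizes.
    """

    windows: pd.DataFrame
    counts: np.ndarray
    samples: pd.DataFrame  # columns: sample, group
    lib_sizes: np.ndarray
    norm_factors: Optional[np.ndarray] = None
    width: int = 200
    step: int = 10

    def __post_init__(self):
        if len(self.windows) != len(self.counts):
            raise ValueError("windows/counts row mismatch")
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.samples):
            raise ValueError("counts column count != sample count")
        if self.norm_factors is not None:
            self._check_factors(self.norm_factors)

    @staticmethod
    def _check_factors(factors: np.ndarray) -> None:
        if np.any(factors <= 0):
            raise ValueError("normalization factors must be strictly positive")
        log_mean = float(np.mean(np.log(factors)))
        if abs(log_mean) > 1e-8:
            raise ValueError("normalization factors must have geometric mean 1")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def effective_lib_sizes(self) -> np.ndarray:
        if self.norm_factors is None:
            return self.lib_sizes.astype(float)
        return self.lib_sizes * self.norm_factors

    def with_factors(self, factors: np.ndarray) -> "WindowCountMatrix":
        factors = np.asarray(factors, dtype=float)
        self._check_factors(factors)
        return replace(self, norm_factors=factors)

    def avg_logcpm(self) -> np.ndarray:
        """Mean across samples of log2 counts-per-million (stabilized)."""
        eff = self.effective_lib_sizes()
        cpm = (self.counts + 0.5) / (eff + 1.0) * 1e6
        return np.log2(cpm).mean(axis=1)

    def subset(self, mask: np.ndarray) -> "WindowCountMatrix":
        return replace(
            self,
            windows=self.windows.loc[mask].reset_index(drop=True),
            counts=self.counts[mask],
        )


def _extended(
    arr: np.ndarray, strands: Optional[np.ndarray], extension: Optional[int], clen: int
) -> np.ndarray:
    """Extend intervals shorter than ``extension`` to that length from their
    5' end (strand-aware; unstranded records are treated as +)."""
    if extension is None or len(arr) == 0:
        return arr
    lengths = arr[:, 1] - arr[:, 0]
    short = lengths < extension
    if not np.any(short):
        return arr
    out = arr.copy()
    if strands is None or len(strands) != len(arr):
        minus = np.zeros(len(arr), dtype=bool)
    else:
        minus = strands == "-"
    plus_short = short & ~minus
    minus_short = short & minus
    out[plus_short, 1] = np.minimum(out[plus_short, 0] + extension, clen)
    out[minus_short, 0] = np.maximum(out[minus_short, 1] - extension, 0)
    return out


def count_windows(
    fragment_sets: Sequence[FragmentSet],
    chrom_sizes: Dict[str, int],
    width: int = 200,
    step: int = 10,
    fragment_extension: Optional[int] = 200,
    groups: Optional[Sequence[str]] = None,
) -> WindowCountMatrix:
    """Count fragments overlapping consecutive overlapping windows.

    Windows start at 0, step, 2*step, ... with start + width <= chromosome
    length; a fragment increments every window it shares >= 1 bp with.
    All-zero windows are dropped from storage (they are logically zero).
    """
    if width <= 0 or not 0 < step <= width:
        raise ValueError("require width > 0 and 0 < step <= width")
    n_samples = len(fragment_sets)
    if n_samples == 0:
        raise ValueError("no fragment sets supplied")

    sample_names, group_names, lib_sizes = [], [], []
    for i, fs in enumerate(fragment_sets):
        fs.validate_sorted()
        for chrom in fs.intervals:
            if chrom not in chrom_sizes:
                raise ValueError(f"fragments on unknown chromosome {chrom!r}")
        sample_names.append(fs.sample or f"sample_{i}")
        group_names.append(fs.group)
        lib_sizes.append(fs.n_fragments())
    if groups is not None:
        group_names = list(groups)

    window_frames = []
    count_blocks = []
    for chrom in chrom_sizes:
        clen = int(chrom_sizes[chrom])
        if clen < width:
            continue
        n_win = (clen - width) // step + 1
        counts = np.zeros((n_win, n_samples), dtype=np.int64)
        for j, fs in enumerate(fragment_sets):
            arr = fs.intervals.get(chrom)
            if arr is None or len(arr) == 0:
                continue
            arr = _extended(arr, fs.strands.get(chrom), fragment_extension, clen)
            # window index range overlapping fragment [s, e):
            # start > s - width and start <= e - 1
            lo = np.maximum((arr[:, 0] - width) // step + 1, 0)
            hi = np.minimum((arr[:, 1] - 1) // step, n_win - 1)
            valid = hi >= lo
            lo, hi = lo[valid], hi[valid]
            delta = np.zeros(n_win + 1, dtype=np.int64)
            np.add.at(delta, lo, 1)
            np.add.at(delta, hi + 1, -1)
            counts[:, j] = np.cumsum(delta[:-1])
        nonzero = counts.sum(axis=1) > 0
        if not np.any(nonzero):
            continue
        starts = (np.flatnonzero(nonzero) * step).astype(np.int64)
        window_frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})
        )
        count_blocks.append(counts[nonzero])

    if window_frames:
        windows = pd.concat(window_frames, ignore_index=True)
        counts = np.vstack(count_blocks)
    else:
        windows = pd.DataFrame(columns=["chrom", "start", "end"])
        counts = np.zeros((0, n_samples), dtype=np.int64)

    samples = pd.DataFrame({"sample": sample_names, "group": group_names})
    return WindowCountMatrix(
        windows=windows,
        counts=counts,
        samples=samples,
        lib_sizes=np.asarray(lib_sizes, dtype=float),
        width=width,
        step=step,
    )


def _normalize_chrom(name: str) -> str:
    name = str(name)
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper()


def filter_windows(
    matrix: WindowCountMatrix,
    min_count_sum: int = 30,
    min_avg_logcpm: float = -1.0,
    excluded_chroms: Iterable[str] = ("X", "Y"),
) -> WindowCountMatrix:
    """Keep windows with count sum >= min_count_sum across samples, average
    logCPM >= min_avg_logcpm, and chromosome outside the excluded set
    (sex chromosomes by default; 'chr' prefixes are tolerated)."""
    if matrix.n_samples < 1:
        raise ValueError("matrix has no samples")
    excluded = {_normalize_chrom(c) for c in excluded_chroms}
    keep = matrix.counts.sum(axis=1) >= min_count_sum
    keep &= matrix.avg_logcpm() >= min_avg_logcpm
    chrom_ok = ~matrix.windows["chrom"].map(_normalize_chrom).isin(excluded)
    keep &= chrom_ok.to_numpy()
    return matrix.subset(keep)
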