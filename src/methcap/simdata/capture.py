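"""MBD-capture fragment simulation.

Candidate molecules are sonication fragments with Normal-distributed
lengths. Each CpG on a molecule is methylated with probability equal to its
(sample-jittered) methylation level; a molecule carrying k methylated CpGs
is retained by the capture step with probability 1 - (1-q)^k, the simplest
per-CpG affinity model in which coverage grows with methylated-CpG content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from methcap.simdata.config import SimulationConfig, substream
from methcap.simdata.genome import GenomeModel
from methcap.simdata.methylome import MethylationProfile


@dataclass
class FragmentSet:
    """Per-sample captured fragments as sorted half-open intervals."""

    intervals: Dict[str, np.ndarray]  # chrom -> (n, 2) int array, sorted
    strands: Dict[str, np.ndarray] = field(default_factory=dict)
    sample: str = ""
    group: str = ""

    def n_fragments(self) -> int:
        return int(sum(len(v) for v in self.intervals.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of fragments overlapping [start, end) by >= 1 bp."""
        arr = self.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            return 0
        overlaps = (arr[:, 0] < end) & (arr[:, 1] > start)
        return int(overlaps.sum())

    def validate_sorted(self) -> None:
        for chrom, arr in self.intervals.items():
            if len(arr) > 1 and np.any(np.diff(arr[:, 0]) < 0):
                raise ValueError(f"fragments on {chrom} are not coordinate-sorted")


def _jittered_levels(
    levels: np.ndarray, rng: np.random.Generator, sd: float
) -> np.ndarray:
    if sd == 0:
        return levels
    return np.clip(levels + rng.normal(0.0, sd, size=len(levels)), 0.0, 1.0)


def simulate_mbd_fragments(
    profile: MethylationProfile,
    genome: GenomeModel,
    config: SimulationConfig,
    group: str,
    sample_index: int,
) -> FragmentSet:
    """Simulate one sample's captured fragment set.

    The candidate molecule total is drawn as negative binomial around
    ``config.fragments_per_sample``; the retained total then varies with the
    genome's methylated-CpG content through the capture-retention model.
    Deterministic given (config.seed, group, sample_index).
    """
    q = config.capture_affinity
    if not 0 < q <= 1:
        raise ValueError("capture_affinity must lie in (0, 1]")
    rng = substream(config.seed, "mbd", group, sample_index)

    sizes = genome.chrom_sizes()
    chrom_names = list(sizes)
    lengths = np.array([sizes[c] for c in chrom_names], dtype=float)

    phi = config.library_size_dispersion
    mean_total = float(config.fragments_per_sample)
    n_candidates = int(
        rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mean_total))
    )
    per_chrom = rng.multinomial(n_candidates, lengths / lengths.sum())

    intervals: Dict[str, np.ndarray] = {}
    strands: Dict[str, np.ndarray] = {}
    for chrom, m in zip(chrom_names, per_chrom):
        if m == 0:
            intervals[chrom] = np.empty((0, 2), dtype=np.int64)
            strands[chrom] = np.empty(0, dtype="U1")
            continue
        clen = sizes[chrom]
        frag_len = rng.normal(config.fragment_length_mean, config.fragment_length_sd, m)
        frag_len = np.maximum(np.round(frag_len), config.min_fragment_length).astype(
            np.int64
        )
        starts = rng.integers(0, clen, size=m)
        ends = np.minimum(starts + frag_len, clen)

        pos = profile.positions[chrom]
        lev = _jittered_levels(
            profile.group_level(group, chrom), rng, config.sample_jitter_sd
        )
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        n_cpg = hi - lo
        total = int(n_cpg.sum())
        k = np.zeros(m, dtype=np.int64)
        if total:
            # flat index of every (fragment, CpG) pair
            frag_of = np.repeat(np.arange(m), n_cpg)
            offset = np.arange(total) - np.repeat(
                np.concatenate(([0], np.cumsum(n_cpg)[:-1])), n_cpg
            )
            cpg_idx = np.repeat(lo, n_cpg) + offset
            methylated = rng.random(total) < lev[cpg_idx]
            np.add.at(k, frag_of, methylated)
        retain_p = 1.0 - (1.0 - q) ** k
        keep = rng.random(m) < retain_p
        kept = np.column_stack([starts[keep], ends[keep]])
        order = np.lexsort((kept[:, 1], kept[:, 0]))
        intervals[chrom] = kept[order]
        strands[chrom] = np.where(rng.random(int(keep.sum())) < 0.5, "+", "-")

    return FragmentSet(
        intervals=intervals,
        strands=strands,
        sample=f"{group}_{sample_index}",
        group=group,
    )
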