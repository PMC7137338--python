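"""Group-level methylation profiles with planted DMRs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable

import numpy as np
import pandas as pd

from methcap.intervals import merge_intervals
from methcap.simdata.config import GROUPS, SimulationConfig, substream
from methcap.simdata.genome import GenomeModel

_TUMOR_GROUPS = frozenset({"primary", "metastasis"})


@dataclass(frozen=True)
class PlantedDMR:
    """A ground-truth differential-methylation event.

    ``delta`` shifts the methylation level of every CpG in the interval for
    the affected tumor groups; levels are clamped to [0, 1] afterwards, so
    the realized shift can be smaller than ``delta`` near the boundaries.
    """

    chrom: str
    start: int
    end: int
    direction: str
    affected_groups: FrozenSet[str]
    delta: float

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.direction == "hyper" and self.delta <= 0:
            raise ValueError("hyper DMR requires delta > 0")
        if self.direction == "hypo" and self.delta >= 0:
            raise ValueError("hypo DMR requires delta < 0")
        if not (-1 <= self.delta <= 1):
            raise ValueError("delta must lie in [-1, 1]")
        groups = frozenset(self.affected_groups)
        if not groups or not groups <= _TUMOR_GROUPS:
            raise ValueError("affected_groups must be a nonempty subset of "
                             "{'primary', 'metastasis'}")
        object.__setattr__(self, "affected_groups", groups)
        if self.end <= self.start:
            raise ValueError("empty DMR interval")


@dataclass
class MethylationProfile:
    """Per-group methylation level at every CpG of the genome."""

    positions: Dict[str, np.ndarray]
    levels: Dict[str, Dict[str, np.ndarray]]  # group -> chrom -> level array

    def groups(self) -> tuple:
        return tuple(self.levels)

    def group_level(self, group: str, chrom: str) -> np.ndarray:
        return self.levels[group][chrom]

    def mean_level(self, group: str, chrom: str, start: int, end: int) -> float:
        pos = self.positions[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        if hi == lo:
            return float("nan")
        return float(self.levels[group][chrom][lo:hi].mean())


def simulate_methylation_profile(
    genome: GenomeModel,
    planted: Iterable[PlantedDMR],
    config: SimulationConfig,
) -> MethylationProfile:
    """Baseline methylome plus planted group-specific shifts.

    Baseline: island CpGs nearly unmethylated, everything else heavily
    methylated (levels drawn per CpG within the configured ranges, shared by
    all groups). Planted DMRs shift only their affected tumor groups; the
    normal group is never shifted.
    """
    planted = list(planted)
    sizes = genome.chrom_sizes()
    for dmr in planted:
        if dmr.chrom not in sizes:
            raise ValueError(f"planted DMR on unknown chromosome {dmr.chrom!r}")
        if dmr.start < 0 or dmr.end > sizes[dmr.chrom]:
            raise ValueError(
                f"planted DMR {dmr.chrom}:{dmr.start}-{dmr.end} outside chromosome"
            )

    rng = substream(config.seed, "profile")
    positions: Dict[str, np.ndarray] = {}
    baseline: Dict[str, np.ndarray] = {}
    for chrom in sizes:
        pos = genome.cpg_positions(chrom)
        positions[chrom] = pos
        lo_bg, hi_bg = config.background_level_range
        lev = rng.uniform(lo_bg, hi_bg, size=len(pos))
        islands = merge_intervals(genome.islands.get(chrom, []))
        if len(islands):
            # CpG is inside an island iff an island start <= pos < its end
            idx = np.searchsorted(islands[:, 0], pos, side="right") - 1
            inside = (idx >= 0) & (pos < islands[np.maximum(idx, 0), 1])
            lo_isl, hi_isl = config.island_level_range
            lev[inside] = rng.uniform(lo_isl, hi_isl, size=int(inside.sum()))
        baseline[chrom] = lev

    levels = {g: {c: baseline[c].copy() for c in baseline} for g in GROUPS}

    # genome-wide tumor drift: a smooth (block-constant) methylation shift
    # of non-island CpGs, shared by both tumor groups
    if config.tumor_drift_sd > 0 or config.tumor_drift_mean != 0:
        drng = substream(config.seed, "drift")
        for chrom in sizes:
            pos = positions[chrom]
            if len(pos) == 0:
                continue
            n_blocks = sizes[chrom] // config.tumor_drift_block + 1
            delta = drng.normal(
                config.tumor_drift_mean, config.tumor_drift_sd, size=n_blocks
            )
            shift = delta[pos // config.tumor_drift_block]
            islands = merge_intervals(genome.islands.get(chrom, []))
            if len(islands):
                idx = np.searchsorted(islands[:, 0], pos, side="right") - 1
                inside = (idx >= 0) & (pos < islands[np.maximum(idx, 0), 1])
                shift = np.where(inside, 0.0, shift)
            for group in ("primary", "metastasis"):
                arr = levels[group][chrom]
                arr[:] = np.clip(arr + shift, 0.0, 1.0)

    for dmr in planted:
        pos = positions[dmr.chrom]
        lo, hi = np.searchsorted(pos, [dmr.start, dmr.end])
        for group in dmr.affected_groups:
            arr = levels[group][dmr.chrom]
            arr[lo:hi] = np.clip(arr[lo:hi] + dmr.delta, 0.0, 1.0)
    return MethylationProfile(positions, levels)


def truth_table(planted: Iterable[PlantedDMR]) -> pd.DataFrame:
    """Planted-truth export: one row per planted DMR."""
    rows = [
        {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "direction": d.direction,
            "affected_groups": ",".join(sorted(d.affected_groups)),
            "delta": d.delta,
        }
        for d in planted
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "affected_groups", "delta"]
    )
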