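"""Targeted bisulfite sequencing count simulation.

Per CpG: total coverage ~ NB(mean coverage, dispersion); methylated count
~ beta-binomial(total, level, rho), collapsing to binomial when rho = 0 or
when the level is exactly 0 or 1.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from methcap.simdata.config import SimulationConfig, substream
from methcap.simdata.methylome import MethylationProfile


def simulate_bisulfite_counts(
    profile: MethylationProfile,
    config: SimulationConfig,
    group: str,
    sample_index: int,
    chroms: Optional[list] = None,
) -> pd.DataFrame:
    """One sample's per-CpG (methylated, total) table.

    Returns a DataFrame with columns chrom, pos, methylated, total, sorted
    by coordinate. Deterministic given (config.seed, group, sample_index).
    """
    if config.bisulfite_coverage <= 0:
        raise ValueError("bisulfite_coverage must be positive")
    rng = substream(config.seed, "bisulfite", group, sample_index)
    rho = config.bisulfite_dispersion
    phi = config.coverage_dispersion
    mean_cov = float(config.bisulfite_coverage)

    frames = []
    for chrom in chroms or list(profile.positions):
        pos = profile.positions[chrom]
        lev = profile.group_level(group, chrom)
        if config.sample_jitter_sd > 0:
            lev = np.clip(
                lev + rng.normal(0.0, config.sample_jitter_sd, size=len(lev)), 0.0, 1.0
            )
        total = rng.negative_binomial(
            1.0 / phi, 1.0 / (1.0 + phi * mean_cov), size=len(pos)
        )
        p = lev.copy()
        if rho > 0:
            interior = (lev > 0) & (lev < 1)
            scale = (1.0 - rho) / rho
            a = lev[interior] * scale
            b = (1.0 - lev[interior]) * scale
            p[interior] = rng.beta(a, b)
        methylated = rng.binomial(total, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "methylated": methylated,
                    "total": total,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "methylated", "total"]
    )
    return out
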