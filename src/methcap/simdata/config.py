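"""Simulation configuration and deterministic random substreams."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

#: Study groups. "normal" is the reference mucosa; planted effects may only
#: touch the two tumor groups.
GROUPS = ("normal", "primary", "metastasis")


def substream(seed: int, *key) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a root seed.

    Key components (strings or ints) are hashed into the spawn key, so each
    (stage, group, sample) combination gets its own stream and adding samples
    never perturbs the draws of earlier ones.
    """
    words = []
    for part in key:
        if isinstance(part, (int, np.integer)):
            words.append(int(part) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(part).encode()))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(words))
    return np.random.Generator(np.random.PCG64(ss))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: 3 normal mucosa, 6 primary
    CRC and 12 liver-metastasis samples; sonicated fragments averaging
    200 bp; capture affinity acting per methylated CpG on the molecule.
    """

    # experimental design
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 3, "primary": 6, "metastasis": 12}
    )

    # genome architecture
    chrom_lengths: tuple = (1_000_000,)
    chrom_names: tuple = ()
    n_genes: int = 40
    island_halfwidth: int = 500
    transition_width: int = 1000  # CpG-density taper flanking each island
    open_sea_patch_length: int = 400  # moderate-CpG open-sea patches
    max_patches_per_gene: int = 8
    utr5_length: int = 300
    body_length: int = 5000
    utr3_length: int = 500
    gc_background: float = 0.40
    gc_island: float = 0.55
    # probability that a nascent CpG is erased (C·G -> C·T), per zone
    background_cpg_depletion: float = 0.95
    transition_cpg_depletion: float = 0.50
    patch_cpg_depletion: float = 0.55

    # methylation baselines (levels drawn uniformly within the range)
    island_level_range: tuple = (0.05, 0.10)
    background_level_range: tuple = (0.75, 0.85)
    #: between-sample biological jitter of methylation levels (sd)
    sample_jitter_sd: float = 0.02
    #: genome-wide methylation drift of tumor groups outside islands,
    #: piecewise constant over blocks (emulates the global low-magnitude
    #: hypomethylation of tumor methylomes); identical in both tumor groups
    tumor_drift_mean: float = 0.0
    tumor_drift_sd: float = 0.0
    tumor_drift_block: int = 2000

    # MBD capture
    fragments_per_sample: int = 60_000  # candidate molecules before capture
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    min_fragment_length: int = 50
    capture_affinity: float = 0.1  # q: per-methylated-CpG retention affinity
    library_size_dispersion: float = 0.05  # NB dispersion of candidate totals

    # targeted bisulfite sequencing
    bisulfite_coverage: float = 30.0
    coverage_dispersion: float = 0.1  # NB dispersion of per-CpG totals
    bisulfite_dispersion: float = 0.02  # beta-binomial intraclass correlation

    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome is required")
        if min(self.chrom_lengths) < 50_000:
            raise ValueError("chromosome length must be >= 50 kb")
        if self.chrom_names and len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        for name, value in [
            ("fragments_per_sample", self.fragments_per_sample),
            ("fragment_length_mean", self.fragment_length_mean),
            ("fragment_length_sd", self.fragment_length_sd),
            ("library_size_dispersion", self.library_size_dispersion),
            ("coverage_dispersion", self.coverage_dispersion),
            ("bisulfite_coverage", self.bisulfite_coverage),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.capture_affinity <= 1:
            raise ValueError("capture_affinity must lie in (0, 1]")
        if self.bisulfite_dispersion < 0 or self.bisulfite_dispersion >= 1:
            raise ValueError("bisulfite_dispersion must lie in [0, 1)")
        if self.sample_jitter_sd < 0:
            raise ValueError("sample_jitter_sd must be nonnegative")
        if self.tumor_drift_sd < 0 or self.tumor_drift_block <= 0:
            raise ValueError("invalid tumor drift parameters")
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        for lo, hi in (self.island_level_range, self.background_level_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("level ranges must satisfy 0 <= lo <= hi <= 1")

    def names(self) -> tuple:
        if self.chrom_names:
            return tuple(self.chrom_names)
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["samples_per_group"] = dict(self.samples_per_group)
        return d
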