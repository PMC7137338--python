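"""Canned synthetic study scenarios.

Each builder returns a fully specified :class:`StudyScenario`: genome,
planted truth, group methylation profiles, and which samples to push through
the MBD-capture and bisulfite generators. The scenarios emulate the study's
structure — island-anchored promoter hypermethylation of large magnitude
(delta +0.5) shared by primary tumors and metastases, and short, low-
magnitude (delta -0.2) open-sea hypomethylation enriched in metastases —
at desk scale (single megabase-size chromosome).

Candidate-library sizes are chosen so that CpG-poor methylated background
stays below the window count-sum filter while islands, transition zones and
open-sea patches rise above it, reproducing the sparse "captured region"
structure of MBD data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from methcap.simdata.bisulfite import simulate_bisulfite_counts
from methcap.simdata.capture import FragmentSet, simulate_mbd_fragments
from methcap.simdata.config import SimulationConfig, substream
from methcap.simdata.genome import GenomeModel, simulate_genome
from methcap.simdata.methylome import (
    MethylationProfile,
    PlantedDMR,
    simulate_methylation_profile,
    truth_table,
)

HYPER_DELTA = 0.5
HYPO_DELTA = -0.2
HYPER_FLANK = 1000  # hyper events cover the island and its full shores


@dataclass
class StudyScenario:
    name: str
    config: SimulationConfig
    genome: GenomeModel
    planted: List[PlantedDMR]
    profile: MethylationProfile
    mbde_samples: Dict[str, int]
    te_samples: Dict[str, int] = field(default_factory=dict)

    def fragment_sets(self) -> List[FragmentSet]:
        out = []
        for group, n in self.mbde_samples.items():
            for i in range(n):
                out.append(
                    simulate_mbd_fragments(self.profile, self.genome, self.config, group, i)
                )
        return out

    def bisulfite_tables(self) -> Dict[str, pd.DataFrame]:
        out = {}
        for group, n in self.te_samples.items():
            for i in range(n):
                out[f"{group}_{i}"] = simulate_bisulfite_counts(
                    self.profile, self.config, group, i
                )
        return out

    def te_groups(self) -> Dict[str, str]:
        return {
            f"{group}_{i}": group
            for group, n in self.te_samples.items()
            for i in range(n)
        }

    def truth(self) -> pd.DataFrame:
        return truth_table(self.planted)


def _flat_islands(genome: GenomeModel) -> List[tuple]:
    out = []
    for chrom in genome.chrom_sizes():
        for start, end in genome.islands.get(chrom, []):
            out.append((chrom, int(start), int(end)))
    return out


def _flat_patches(genome: GenomeModel) -> List[tuple]:
    out = []
    for chrom in genome.chrom_sizes():
        for start, end in genome.open_sea_patches.get(chrom, []):
            out.append((chrom, int(start), int(end)))
    return out


def _pick(rng: np.random.Generator, items: List[tuple], k: int) -> List[tuple]:
    k = min(k, len(items))
    idx = np.sort(rng.choice(len(items), size=k, replace=False))
    return [items[i] for i in idx]


def _make_config(overrides, **defaults) -> SimulationConfig:
    if overrides:
        unknown = set(overrides) - set(SimulationConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        defaults.update(overrides)
    if "chrom_lengths" in defaults:
        defaults["chrom_lengths"] = tuple(defaults["chrom_lengths"])
    return SimulationConfig(**defaults)


def _plant_hyper(genome, rng, n, groups) -> List[PlantedDMR]:
    sizes = genome.chrom_sizes()
    picks = _pick(rng, _flat_islands(genome), n)
    return [
        PlantedDMR(
            chrom,
            max(0, start - HYPER_FLANK),
            min(sizes[chrom], end + HYPER_FLANK),
            "hyper",
            frozenset(groups),
            HYPER_DELTA,
        )
        for chrom, start, end in picks
    ]


def _plant_hypo(genome, rng, n, groups, expand: int = 150) -> List[PlantedDMR]:
    sizes = genome.chrom_sizes()
    picks = _pick(rng, _flat_patches(genome), n)
    return [
        PlantedDMR(
            chrom,
            max(0, start - expand),
            min(sizes[chrom], end + expand),
            "hypo",
            frozenset(groups),
            HYPO_DELTA,
        )
        for chrom, start, end in picks
    ]


def null_scenario(seed: int = 0, overrides=None) -> StudyScenario:
    """No planted effects; 3 vs 3 samples. Used for type-I error checks."""
    config = _make_config(
        overrides,
        samples_per_group={"normal": 3, "primary": 3},
        chrom_lengths=(500_000,),
        n_genes=20,
        fragments_per_sample=60_000,
        seed=seed,
    )
    genome = simulate_genome(config)
    profile = simulate_methylation_profile(genome, [], config)
    return StudyScenario(
        "null", config, genome, [], profile,
        mbde_samples=dict(config.samples_per_group),
    )


def recovery_scenario(seed: int = 0, n_hyper: int = 50, overrides=None) -> StudyScenario:
    """Strong island hypermethylation shared by both tumor groups."""
    config = _make_config(
        overrides,
        samples_per_group={"normal": 3, "primary": 6},
        chrom_lengths=(4_000_000,),
        n_genes=55,
        fragments_per_sample=150_000,
        seed=seed,
    )
    genome = simulate_genome(config)
    rng = substream(seed, "plant", "recovery")
    planted = _plant_hyper(genome, rng, n_hyper, {"primary", "metastasis"})
    profile = simulate_methylation_profile(genome, planted, config)
    return StudyScenario(
        "recovery",
        config,
        genome,
        planted,
        profile,
        mbde_samples=dict(config.samples_per_group),
    )


def tumor_scenario(
    seed: int = 0,
    n_hyper: int = 30,
    n_hypo: int = 40,
    shared_hypo: bool = False,
    overrides=None,
) -> StudyScenario:
    """Full three-group design: shared hyper DMRs plus short low-magnitude
    hypo DMRs that by default affect only the metastases.

    With ``shared_hypo=True`` every planted effect is identical in the two
    tumor groups, so the metastasis-vs-primary contrast is a true null.
    """
    config = _make_config(
        overrides,
        samples_per_group={"normal": 3, "primary": 6, "metastasis": 12},
        chrom_lengths=(3_300_000,),
        n_genes=45,
        fragments_per_sample=1_600_000,
        background_cpg_depletion=0.9995,
        seed=seed,
    )
    genome = simulate_genome(config)
    rng = substream(seed, "plant", "tumor")
    planted = _plant_hyper(genome, rng, n_hyper, {"primary", "metastasis"})
    hypo_groups = {"primary", "metastasis"} if shared_hypo else {"metastasis"}
    planted += _plant_hypo(genome, rng, n_hypo, hypo_groups)
    profile = simulate_methylation_profile(genome, planted, config)
    return StudyScenario(
        "tumor",
        config,
        genome,
        planted,
        profile,
        mbde_samples=dict(config.samples_per_group),
    )


def crossplatform_scenario(
    seed: int = 0, n_hyper: int = 30, n_hypo: int = 30, overrides=None
) -> StudyScenario:
    """Shared latent methylome pushed through both generators.

    Primary-vs-normal effects only: island-anchored hyper DMRs spilling into
    their shores plus short open-sea hypo DMRs, so every CpG-density stratum
    carries shared signal. MBDE uses the sequencing design; TE mirrors the
    emulated 3-vs-3 targeted bisulfite study.
    """
    config = _make_config(
        overrides,
        samples_per_group={"normal": 3, "primary": 6},
        chrom_lengths=(2_500_000,),
        n_genes=35,
        fragments_per_sample=250_000,
        max_patches_per_gene=1,
        patch_cpg_depletion=0.75,
        tumor_drift_mean=-0.05,
        tumor_drift_sd=0.15,
        seed=seed,
    )
    genome = simulate_genome(config)
    rng = substream(seed, "plant", "crossplatform")
    planted = _plant_hyper(genome, rng, n_hyper, {"primary"})
    planted += _plant_hypo(genome, rng, n_hypo, {"primary"})
    profile = simulate_methylation_profile(genome, planted, config)
    return StudyScenario(
        "crossplatform",
        config,
        genome,
        planted,
        profile,
        mbde_samples=dict(config.samples_per_group),
        te_samples={"normal": min(3, config.samples_per_group.get("normal", 0)),
                    "primary": min(3, config.samples_per_group.get("primary", 0))},
    )
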