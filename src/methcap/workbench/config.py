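"""Pipeline configuration schema (strict: unknown keys are rejected)."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field


class StageParams(BaseModel):
    """Analysis-stage parameters with the study defaults."""

    model_config = ConfigDict(extra="forbid")

    width: int = 200
    step: int = 10
    fragment_extension: Optional[int] = 200
    min_count_sum: int = 30
    min_avg_logcpm: float = -1.0
    excluded_chroms: Tuple[str, ...] = ("X", "Y")
    max_gap: int = 50
    fdr_cutoff: float = 0.05
    norm: str = "tmm"
    norm_bin_width: int = 10_000
    prior_df: float = 10.0
    upstream: int = 5000
    shore_width: int = 2000
    shelf_width: int = 2000
    density_window: int = 200
    density_low: float = 0.3
    density_high: float = 0.6
    alpha: float = 0.05


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    outdir: str
    seed: int = 0
    #: which canned scenario the simulate stage builds
    scenario: str = "crossplatform"
    #: SimulationConfig field overrides for the simulate stage
    simulation: Dict = Field(default_factory=dict)
    #: contrasts to test, as [tumor, reference] pairs
    contrasts: List[Tuple[str, str]] = Field(
        default_factory=lambda: [("primary", "normal")]
    )
    stages: List[str] = Field(
        default_factory=lambda: ["simulate", "test", "annotate", "compare"]
    )
    params: StageParams = Field(default_factory=StageParams)

    # explicit input paths when the simulate stage is disabled
    genome_fasta: Optional[str] = None
    islands_bed: Optional[str] = None
    genes_tsv: Optional[str] = None
    sample_sheet: Optional[str] = None
    chrom_sizes: Optional[str] = None
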