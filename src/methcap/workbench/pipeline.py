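"""Pipeline orchestration: simulate -> count/test -> annotate -> compare.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so stages can be re-run individually. A manifest records stage
parameters, output file hashes, the package version and timestamps;
deterministic stages reproduce identical hashes under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from methcap import __version__
from methcap.annotation import RegionAnnotator, classify_cpg_density
from methcap.crossplatform import (
    CpGBetaRegression,
    classify_cpgs,
    correlate_methods,
    propagate_region_stats,
)
from methcap.mbd_dmr import DMRCaller
from methcap.simdata import scenarios as sc
from methcap.simdata.genome import GenomeModel
from methcap.workbench import io
from methcap.workbench.config import PipelineConfig

_SCENARIOS = {
    "null": sc.null_scenario,
    "recovery": sc.recovery_scenario,
    "tumor": sc.tumor_scenario,
    "crossplatform": sc.crossplatform_scenario,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    stages: List[dict] = dataclasses.field(default_factory=list)

    def record(self, stage: str, outputs: List[Path], t0: float) -> None:
        self.stages.append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
                "seconds": round(time.time() - t0, 3),
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "config": self.config, "stages": self.stages},
                fh,
                indent=2,
                default=str,
            )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.model_dump(), version=__version__)

    stage = "validate"
    try:
        if config.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {config.scenario!r}")
        scenario = None
        if "simulate" in config.stages:
            stage = "simulate"
            scenario = _run_simulate(config, outdir, manifest)
        if "test" in config.stages:
            stage = "test"
            _run_test(config, outdir, manifest)
        if "annotate" in config.stages:
            stage = "annotate"
            _run_annotate(config, outdir, manifest)
        if "compare" in config.stages:
            stage = "compare"
            _run_compare(config, outdir, manifest, scenario)
    except Exception as exc:  # halt with the failing stage named
        raise StageError(stage, exc) from exc

    manifest.write(outdir / "manifest.json")
    return manifest


def _build_scenario(config: PipelineConfig):
    builder = _SCENARIOS[config.scenario]
    return builder(seed=config.seed, overrides=config.simulation or None)


def _run_simulate(config: PipelineConfig, outdir: Path, manifest: RunManifest):
    t0 = time.time()
    scenario = _build_scenario(config)
    genome = scenario.genome
    outputs = []

    p = outdir / "genome.fa"
    io.write_fasta(genome, p)
    outputs.append(p)
    p = outdir / "islands.bed"
    io.write_bed(genome.islands, p, name="island")
    outputs.append(p)
    p = outdir / "genes.tsv"
    io.write_genes_tsv(genome.genes, p)
    outputs.append(p)
    p = outdir / "chrom_sizes.tsv"
    io.write_chrom_sizes(genome.chrom_sizes(), p)
    outputs.append(p)
    p = outdir / "truth.tsv"
    scenario.truth().to_csv(p, sep="\t", index=False)
    outputs.append(p)

    rows = []
    for fs in scenario.fragment_sets():
        path = outdir / f"fragments_{fs.sample}.bed"
        io.write_fragments_bed(fs, path)
        outputs.append(path)
        rows.append({"sample": fs.sample, "group": fs.group, "path": path.name})
    sheet = pd.DataFrame(rows)
    p = outdir / "sample_sheet.tsv"
    io.write_sample_sheet(sheet, p)
    outputs.append(p)

    for sample, table in scenario.bisulfite_tables().items():
        path = outdir / f"bisulfite_{sample}.tsv"
        io.write_bisulfite_tsv(table, path)
        outputs.append(path)
    if scenario.te_samples:
        te_sheet = pd.DataFrame(
            [
                {"sample": s, "group": g, "path": f"bisulfite_{s}.tsv"}
                for s, g in scenario.te_groups().items()
            ]
        )
        p = outdir / "te_sample_sheet.tsv"
        io.write_sample_sheet(te_sheet, p)
        outputs.append(p)

    manifest.record("simulate", outputs, t0)
    return scenario


def _load_fragments(outdir: Path):
    sheet = io.read_sample_sheet(outdir / "sample_sheet.tsv")
    sets = [
        io.read_fragments_bed(outdir / r.path, sample=r.sample, group=r.group)
        for r in sheet.itertuples()
    ]
    return sheet, sets


def _run_test(config: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    sheet, sets = _load_fragments(outdir)
    chrom_sizes = io.read_chrom_sizes(outdir / "chrom_sizes.tsv")
    p = config.params
    outputs = []
    caller = None
    dispersion = None
    for tumor, ref in config.contrasts:
        caller = DMRCaller(
            contrast=(tumor, ref),
            width=p.width,
            step=p.step,
            fragment_extension=p.fragment_extension,
            min_count_sum=p.min_count_sum,
            min_avg_logcpm=p.min_avg_logcpm,
            excluded_chroms=p.excluded_chroms,
            max_gap=p.max_gap,
            fdr_cutoff=p.fdr_cutoff,
            norm=p.norm,
            norm_bin_width=p.norm_bin_width,
            prior_df=p.prior_df,
        )
        caller.fit(
            sets, y=list(sheet["group"]), chrom_sizes=chrom_sizes, dispersion=dispersion
        )
        if dispersion is None:
            # reuse the full-design dispersion across contrasts
            dispersion = caller.window_results_["dispersion"].to_numpy()
        tag = f"{tumor}_vs_{ref}"
        path = outdir / f"windows_{tag}.tsv"
        caller.window_results_.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        path = outdir / f"regions_{tag}.bed"
        io.write_regions_bed(caller.regions_, path)
        outputs.append(path)
    manifest.record("test", outputs, t0)


def _load_genome(outdir: Path) -> GenomeModel:
    chroms = io.read_fasta(outdir / "genome.fa")
    islands = io.intervals_from_bed(io.read_bed(outdir / "islands.bed"))
    genes = io.read_genes_tsv(outdir / "genes.tsv")
    return GenomeModel(chroms, islands, genes)


def _run_annotate(config: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    genome = _load_genome(outdir)
    p = config.params
    annotator = RegionAnnotator(
        upstream=p.upstream, shore_width=p.shore_width, shelf_width=p.shelf_width
    ).fit(genome)
    outputs = []
    for tumor, ref in config.contrasts:
        tag = f"{tumor}_vs_{ref}"
        regions = io.read_regions_bed(outdir / f"regions_{tag}.bed")
        annotated = annotator.transform(regions)
        path = outdir / f"regions_{tag}_annotated.tsv"
        annotated.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    density = classify_cpg_density(genome, window=p.density_window)
    path = outdir / "cpg_density.tsv"
    density.to_csv(path, sep="\t", index=False)
    outputs.append(path)
    manifest.record("annotate", outputs, t0)


def _run_compare(
    config: PipelineConfig, outdir: Path, manifest: RunManifest, scenario
) -> None:
    te_sheet_path = outdir / "te_sample_sheet.tsv"
    if not te_sheet_path.exists():
        return  # nothing to compare against
    t0 = time.time()
    te_sheet = io.read_sample_sheet(te_sheet_path)
    tables = {
        r.sample: io.read_bisulfite_tsv(outdir / r.path) for r in te_sheet.itertuples()
    }
    first = next(iter(tables.values()))
    sites = first[["chrom", "pos"]].reset_index(drop=True)
    meth = np.column_stack([tables[s]["methylated"] for s in te_sheet["sample"]])
    total = np.column_stack([tables[s]["total"] for s in te_sheet["sample"]])

    tumor, ref = config.contrasts[0]
    model = CpGBetaRegression(contrast=(tumor, ref))
    model.fit((sites, meth, total), list(te_sheet["group"]))
    te = model.results_.rename(columns={"diff": "te_diff", "pvalue": "te_p"})

    regions = io.read_regions_bed(outdir / f"regions_{tumor}_vs_{ref}.bed")
    propagated = propagate_region_stats(regions, te)
    records = te.merge(propagated, on=["chrom", "pos"])
    density = pd.read_csv(outdir / "cpg_density.tsv", sep="\t")
    records = records.merge(density[["chrom", "pos", "density_class"]], on=["chrom", "pos"])
    both = records[records["mbde_covered"]].reset_index(drop=True)
    both = classify_cpgs(both, alpha=config.params.alpha)

    outputs = []
    path = outdir / "concordance_cpgs.tsv"
    both.to_csv(path, sep="\t", index=False)
    outputs.append(path)
    summary = correlate_methods(both)
    path = outdir / "concordance_summary.tsv"
    summary.per_stratum.to_csv(path, sep="\t", index=False)
    outputs.append(path)
    manifest.record("compare", outputs, t0)
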