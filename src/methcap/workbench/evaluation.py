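"""End-to-end evaluation of the canned synthetic scenarios.

Each function simulates a scenario, runs the full analysis through the
library, and measures the study-level quantities of interest (type-I error,
DMR recovery and direction accuracy, contrast overlap structure,
cross-platform concordance). Used by the acceptance checks and by the
reproduction script.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from methcap.annotation import classify_cpg_density
from methcap.crossplatform import (
    CpGBetaRegression,
    classify_cpgs,
    correlate_methods,
    overlap_dmrs,
    propagate_region_stats,
)
from methcap.mbd_dmr import DMRCaller
from methcap.simdata import scenarios as sc


def _covers(dmrs: pd.DataFrame, chrom: str, start: int, end: int,
            direction: str = None) -> bool:
    sub = dmrs[(dmrs["chrom"] == chrom) & (dmrs["start"] < end) & (dmrs["end"] > start)]
    if direction is not None:
        sub = sub[sub["direction"] == direction]
    return len(sub) > 0


def evaluate_null(seed: int) -> Dict[str, float]:
    """Type-I error of the window tests and the region FDR gate on a
    3-vs-3 null study."""
    scenario = sc.null_scenario(seed=seed)
    caller = DMRCaller(contrast=("primary", "normal"))
    caller.fit(scenario.fragment_sets(), chrom_sizes=scenario.genome.chrom_sizes())
    w = caller.window_results_
    r = caller.regions_
    return {
        "n_windows": int(len(w)),
        "window_p_lt_05_fraction": float((w["pvalue"] < 0.05).mean()),
        "n_regions": int(len(r)),
        "flagged_region_fraction": float(r["significant"].mean()) if len(r) else 0.0,
    }


def evaluate_recovery(seed: int) -> Dict[str, float]:
    """Recovery of 50 strong island hyper DMRs at FDR 0.05 (>= 1-bp
    overlap with truth) and direction accuracy among recovered regions."""
    scenario = sc.recovery_scenario(seed=seed)
    caller = DMRCaller(contrast=("primary", "normal"))
    caller.fit(scenario.fragment_sets(), chrom_sizes=scenario.genome.chrom_sizes())
    dmrs = caller.dmrs_
    truth = scenario.truth()
    recovered = correct = 0
    for t in truth.itertuples():
        if _covers(dmrs, t.chrom, t.start, t.end):
            recovered += 1
            if _covers(dmrs, t.chrom, t.start, t.end, direction=t.direction):
                correct += 1
    return {
        "n_planted": int(len(truth)),
        "n_flagged": int(len(dmrs)),
        "recovery_fraction": recovered / len(truth),
        "direction_accuracy": correct / recovered if recovered else float("nan"),
    }


def evaluate_tumor(seed: int, shared_hypo: bool = False) -> Dict[str, float]:
    """Three-group study: per-contrast DMR calls, hyper-DMR overlap between
    the two tumor-vs-normal contrasts, hypo-DMR enrichment in metastases,
    and the metastasis-vs-primary contrast."""
    scenario = sc.tumor_scenario(seed=seed, shared_hypo=shared_hypo)
    sizes = scenario.genome.chrom_sizes()
    fragment_sets = scenario.fragment_sets()
    primary = DMRCaller(contrast=("primary", "normal"))
    primary.fit(fragment_sets, chrom_sizes=sizes)
    dispersion = primary.window_results_["dispersion"].to_numpy()
    met = DMRCaller(contrast=("metastasis", "normal"))
    met.fit(primary.matrix_, dispersion=dispersion)
    stage = DMRCaller(contrast=("metastasis", "primary"))
    stage.fit(primary.matrix_, dispersion=dispersion)

    d_p, d_m = primary.dmrs_, met.dmrs_
    hyper_p = d_p[d_p["direction"] == "hyper"]
    hyper_m = d_m[d_m["direction"] == "hyper"]
    ov_hyper = overlap_dmrs(hyper_p, hyper_m)
    hypo_p = d_p[d_p["direction"] == "hypo"]
    hypo_m = d_m[d_m["direction"] == "hypo"]
    ov_hypo = overlap_dmrs(hypo_p, hypo_m)
    hypo_union = len(hypo_p) + len(hypo_m) - len(ov_hypo.both_b)
    hyper_union = len(hyper_p) + len(hyper_m) - len(ov_hyper.both_b)

    truth = scenario.truth()
    hypo_truth = truth[truth["direction"] == "hypo"]
    recovered_hypo = sum(
        _covers(hypo_m, t.chrom, t.start, t.end) for t in hypo_truth.itertuples()
    )
    return {
        "n_dmrs_primary": int(len(d_p)),
        "n_dmrs_met": int(len(d_m)),
        "hyper_fraction_primary": float((d_p["direction"] == "hyper").mean())
        if len(d_p) else float("nan"),
        "hyper_fraction_met": float((d_m["direction"] == "hyper").mean())
        if len(d_m) else float("nan"),
        "hyper_overlap_primary_in_met": len(ov_hyper.both_a) / max(len(hyper_p), 1),
        "hyper_overlap_met_in_primary": len(ov_hyper.both_b) / max(len(hyper_m), 1),
        "hyper_shared_fraction": (len(ov_hyper.both_b) / hyper_union)
        if hyper_union else float("nan"),
        "n_hypo_primary": int(len(hypo_p)),
        "n_hypo_met": int(len(hypo_m)),
        "hypo_met_only_fraction": ((len(hypo_m) - len(ov_hypo.both_b)) / hypo_union)
        if hypo_union else float("nan"),
        "hypo_recovery_fraction": recovered_hypo / max(len(hypo_truth), 1),
        "met_vs_primary_flagged_fraction": float(stage.regions_["significant"].mean())
        if len(stage.regions_) else 0.0,
        "n_regions": int(len(primary.regions_)),
    }


def evaluate_crossplatform(seed: int) -> Dict[str, float]:
    """MBD-capture vs targeted-bisulfite concordance on a shared latent
    methylome: per-CpG TE calls, MBDE region flags on hypo intervals, and
    density-stratified Pearson correlation."""
    scenario = sc.crossplatform_scenario(seed=seed)
    sizes = scenario.genome.chrom_sizes()
    caller = DMRCaller(contrast=("primary", "normal"))
    caller.fit(scenario.fragment_sets(), chrom_sizes=sizes)

    tables = scenario.bisulfite_tables()
    te_groups = scenario.te_groups()
    names = list(tables)
    sites = tables[names[0]][["chrom", "pos"]]
    meth = np.column_stack([tables[n]["methylated"] for n in names]).astype(float)
    total = np.column_stack([tables[n]["total"] for n in names]).astype(float)
    model = CpGBetaRegression(contrast=("primary", "normal"))
    model.fit((sites, meth, total), [te_groups[n] for n in names])
    te = model.results_.rename(columns={"diff": "te_diff", "pvalue": "te_p"})

    truth = scenario.truth()
    hypo_truth = truth[truth["direction"] == "hypo"]
    pos = te["pos"].to_numpy()
    hypo_cpg = np.zeros(len(te), dtype=bool)
    for t in hypo_truth.itertuples():
        hypo_cpg |= (pos >= t.start) & (pos < t.end)
    te_hypo_call_rate = float((te.loc[hypo_cpg, "te_diff"] < 0).mean())

    dmrs = caller.dmrs_
    mbde_hypo_flagged = sum(
        _covers(dmrs, t.chrom, t.start, t.end, direction="hypo")
        for t in hypo_truth.itertuples()
    )

    propagated = propagate_region_stats(caller.regions_, te)
    records = te.merge(propagated, on=["chrom", "pos"])
    density = classify_cpg_density(scenario.genome)
    records = records.merge(
        density[["chrom", "pos", "density_class"]], on=["chrom", "pos"]
    )
    both = records[records["mbde_covered"]].reset_index(drop=True)
    both = classify_cpgs(both)
    summary = correlate_methods(both)
    per = summary.per_stratum.set_index("density_class")

    out = {
        "n_hypo_planted": int(len(hypo_truth)),
        "n_hypo_cpgs": int(hypo_cpg.sum()),
        "te_hypo_call_rate": te_hypo_call_rate,
        "mbde_hypo_flagged_fraction": mbde_hypo_flagged / max(len(hypo_truth), 1),
        "n_both_covered_cpgs": int(summary.n_total),
        "pearson_r_overall": float(summary.overall_r),
    }
    for stratum in ("low", "intermediate", "high"):
        if stratum in per.index:
            out[f"pearson_r_{stratum}"] = float(per.loc[stratum, "pearson_r"])
            out[f"n_{stratum}"] = int(per.loc[stratum, "n"])
        else:
            out[f"pearson_r_{stratum}"] = float("nan")
            out[f"n_{stratum}"] = 0
    return out
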