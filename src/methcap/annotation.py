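"""Genomic and CpG-density annotation layers.

Two classification families are supported, mirroring common practice for
methylome studies:

* genic: ``regulatory`` (5 kb upstream of the TSS plus the 5'UTR),
  ``gene_body`` (end of 5'UTR to start of 3'UTR) and ``utr3``; anything
  else is extragenic.
* CpG: ``island``, ``shore`` (2 kb flanks) and ``shelf`` (next 2 kb), the
  composite being an sSISs (shelf-shore-island-shore-shelf) region;
  anything else is extra-sSISs (open sea).

CpG density is the classical observed/expected CpG ratio in a 200-bp
window centered on each CpG, classed low (< 0.3), intermediate ([0.3, 0.6))
or high (>= 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from methcap.intervals import (
    clip_intervals,
    intersect_length,
    merge_intervals,
    subtract_intervals,
)
from methcap.simdata.genome import GeneModel, GenomeModel

GENIC_LAYERS = ("regulatory", "gene_body", "utr3")
CPG_LAYERS = ("island", "shore", "shelf")
DENSITY_LOW = 0.3
DENSITY_HIGH = 0.6


@dataclass
class AnnotationSet:
    """Labeled interval layers, per chromosome; intervals merged within a
    layer, and the island/shore/shelf family pairwise disjoint by
    construction (precedence island > shore > shelf)."""

    layers: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)

    def layer(self, name: str, chrom: str) -> np.ndarray:
        return self.layers.get(name, {}).get(chrom, np.empty((0, 2), dtype=np.int64))

    def update(self, other: "AnnotationSet") -> "AnnotationSet":
        self.layers.update(other.layers)
        return self


@dataclass
class CategoryCall:
    genic_class: str  # intragenic | extragenic
    genic_subclass: str  # regulatory | gene_body | utr3 | none
    cpg_class: str  # sSISs | extra_sSISs
    cpg_subclass: str  # island | shore | shelf | none


def build_intragenic_layers(
    genes: Sequence[GeneModel],
    upstream: int = 5000,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> AnnotationSet:
    """Regulatory / gene-body / 3'UTR layers from gene models.

    Regulatory is strand-aware: [TSS - upstream, TSS) on +, [TSS, TSS +
    upstream) on -, unioned with the 5'UTR. Overlapping intervals within a
    layer are merged.
    """
    raw: Dict[str, Dict[str, List[tuple]]] = {k: {} for k in GENIC_LAYERS}
    for g in genes:
        if g.strand == "+":
            up = (g.tss - upstream, g.tss)
        else:
            up = (g.tss, g.tss + upstream)
        for layer, iv in (
            ("regulatory", up),
            ("regulatory", tuple(g.utr5)),
            ("gene_body", tuple(g.body)),
            ("utr3", tuple(g.utr3)),
        ):
            raw[layer].setdefault(g.chrom, []).append(iv)
    out = AnnotationSet()
    for layer, per_chrom in raw.items():
        merged = {}
        for chrom, ivs in per_chrom.items():
            hi = chrom_sizes[chrom] if chrom_sizes else max(e for _, e in ivs)
            merged[chrom] = merge_intervals(clip_intervals(ivs, 0, hi))
        out.layers[layer] = merged
    return out


def build_ssiss_layers(
    islands: Dict[str, Iterable],
    shore_width: int = 2000,
    shelf_width: int = 2000,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> AnnotationSet:
    """Island / shore / shelf layers with precedence island > shore > shelf.

    Shores are the ``shore_width`` flanks of (merged) islands minus the
    islands; shelves the next ``shelf_width`` band minus islands and
    shores. Flanks of adjacent islands fuse, so an inter-island gap
    narrower than two shore widths is entirely shore.
    """
    out = AnnotationSet(layers={k: {} for k in CPG_LAYERS})
    for chrom, ivs in islands.items():
        isl = merge_intervals(ivs)
        hi = chrom_sizes[chrom] if chrom_sizes else (isl[-1, 1] + shore_width + shelf_width if len(isl) else 0)
        shore_zone = (
            merge_intervals(
                np.column_stack([isl[:, 0] - shore_width, isl[:, 1] + shore_width])
            )
            if len(isl)
            else isl
        )
        shelf_zone = (
            merge_intervals(
                np.column_stack(
                    [
                        isl[:, 0] - shore_width - shelf_width,
                        isl[:, 1] + shore_width + shelf_width,
                    ]
                )
            )
            if len(isl)
            else isl
        )
        out.layers["island"][chrom] = clip_intervals(isl, 0, hi)
        out.layers["shore"][chrom] = clip_intervals(
            subtract_intervals(shore_zone, isl), 0, hi
        )
        out.layers["shelf"][chrom] = clip_intervals(
            subtract_intervals(shelf_zone, shore_zone), 0, hi
        )
    return out


def _classify_family(
    chrom: str,
    start: int,
    end: int,
    annotation: AnnotationSet,
    layer_order: Sequence[str],
) -> str:
    """Largest-overlap layer, ties broken by the fixed layer order; 'none'
    when nothing overlaps by >= 1 bp."""
    best, best_len = "none", 0
    for layer in layer_order:
        length = intersect_length(start, end, annotation.layer(layer, chrom))
        if length > best_len:
            best, best_len = layer, length
    return best


def classify_region(
    chrom: str, start: int, end: int, annotation: AnnotationSet
) -> CategoryCall:
    """Assign genic and CpG categories to a region (>= 1 bp overlap rule)."""
    genic_sub = _classify_family(chrom, start, end, annotation, GENIC_LAYERS)
    cpg_sub = _classify_family(chrom, start, end, annotation, CPG_LAYERS)
    return CategoryCall(
        genic_class="intragenic" if genic_sub != "none" else "extragenic",
        genic_subclass=genic_sub,
        cpg_class="sSISs" if cpg_sub != "none" else "extra_sSISs",
        cpg_subclass=cpg_sub,
    )


def classify_regions(regions: pd.DataFrame, annotation: AnnotationSet) -> pd.DataFrame:
    """Vectorized-ish wrapper: one CategoryCall per region row, appended as
    columns."""
    calls = [
        classify_region(r.chrom, int(r.start), int(r.end), annotation)
        for r in regions.itertuples()
    ]
    out = regions.copy()
    out["genic_class"] = [c.genic_class for c in calls]
    out["genic_subclass"] = [c.genic_subclass for c in calls]
    out["cpg_class"] = [c.cpg_class for c in calls]
    out["cpg_subclass"] = [c.cpg_subclass for c in calls]
    return out


def oe_cpg_ratio(sequence: str) -> float:
    """Observed/expected CpG ratio of a sequence.

    observed = count of CG dinucleotides; expected = (#C * #G) / length.
    N bases count toward length but not composition. Returns 0 when the
    expected count is 0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    observed = seq.count("CG")
    expected = seq.count("C") * seq.count("G") / len(seq)
    if expected == 0:
        return 0.0
    return observed / expected


def density_class(ratio: np.ndarray) -> np.ndarray:
    """low (< 0.3) / intermediate ([0.3, 0.6)) / high (>= 0.6)."""
    ratio = np.asarray(ratio, dtype=float)
    out = np.full(ratio.shape, "intermediate", dtype=object)
    out[ratio < DENSITY_LOW] = "low"
    out[ratio >= DENSITY_HIGH] = "high"
    return out


def classify_cpg_density(genome: GenomeModel, window: int = 200) -> pd.DataFrame:
    """O:E CpG ratio and density class for every CpG of the genome.

    Each CpG (position of its C) is centered in a ``window``-bp window,
    clipped at chromosome ends; the ratio is computed from prefix sums so
    the whole genome is processed vectorized.
    """
    half = window // 2
    frames = []
    for chrom_obj in genome.chromosomes:
        chrom = chrom_obj.name
        seq = np.frombuffer(chrom_obj.sequence.encode(), dtype=np.uint8)
        n = len(seq)
        pos = genome.cpg_positions(chrom)
        if len(pos) == 0:
            continue
        is_c = np.concatenate(([0], np.cumsum(seq == ord("C"))))
        is_g = np.concatenate(([0], np.cumsum(seq == ord("G"))))
        cg = np.zeros(n, dtype=np.int64)
        cg[pos] = 1  # CG dinucleotide counted at its C position
        cg_cum = np.concatenate(([0], np.cumsum(cg)))
        lo = np.maximum(pos - half, 0)
        hi = np.minimum(pos + half, n)
        length = (hi - lo).astype(float)
        n_c = is_c[hi] - is_c[lo]
        n_g = is_g[hi] - is_g[lo]
        # a CG pair counts only if both bases fall inside the window, i.e.
        # its C position lies in [lo, hi - 1)
        obs = cg_cum[hi - 1] - cg_cum[lo]
        expected = n_c * n_g / length
        ratio = np.where(expected > 0, obs / np.maximum(expected, 1e-300), 0.0)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "oe_ratio": ratio,
                 "density_class": density_class(ratio)}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "oe_ratio", "density_class"])
    return pd.concat(frames, ignore_index=True)


class RegionAnnotator(BaseEstimator, TransformerMixin):
    """Transformer attaching genic and CpG-density categories to regions.

    fit() builds the layers from a :class:`GenomeModel` (or explicit genes
    and islands); transform() appends CategoryCall columns to a region
    table.
    """

    def __init__(self, upstream: int = 5000, shore_width: int = 2000,
                 shelf_width: int = 2000):
        self.upstream = upstream
        self.shore_width = shore_width
        self.shelf_width = shelf_width

    def fit(self, X: GenomeModel, y=None) -> "RegionAnnotator":
        sizes = X.chrom_sizes()
        self.annotation_ = build_intragenic_layers(
            X.genes, upstream=self.upstream, chrom_sizes=sizes
        ).update(
            build_ssiss_layers(
                X.islands,
                shore_width=self.shore_width,
                shelf_width=self.shelf_width,
                chrom_sizes=sizes,
            )
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return classify_regions(X, self.annotation_)
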