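"""Synthetic genome generation: sequence, CpG islands, genes.

The generated genome alternates gene "slots" along each chromosome. Each
slot carries one gene whose promoter sits on a CpG island (GC-rich, no CpG
depletion, so the island's observed/expected CpG ratio is ~1), a tapering
transition zone flanking the island (partial depletion, shore-like CpG
density) and one moderate-CpG "open-sea patch" well away from the gene.
Everything else is CpG-depleted background, emulating the global CpG
deficit of vertebrate DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from methcap.intervals import as_interval_array, merge_intervals
from methcap.simdata.config import SimulationConfig, substream

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_SLOT = 18_000  # minimum per-gene slot able to host gene + island + patch


@dataclass
class Chromosome:
    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A simple gene: TSS with 5'UTR, body and 3'UTR, strand-aware."""

    chrom: str
    strand: str
    tss: int
    utr5: tuple
    body: tuple
    utr3: tuple

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        order = (self.utr5, self.body, self.utr3)
        if self.strand == "-":
            order = (self.utr3, self.body, self.utr5)
        prev_end = None
        for start, end in order:
            if end <= start:
                raise ValueError("gene feature interval is empty or inverted")
            if prev_end is not None and start != prev_end:
                raise ValueError("gene features must be contiguous in genomic order")
            prev_end = end

    @property
    def span(self) -> tuple:
        coords = [*self.utr5, *self.body, *self.utr3]
        return (min(coords), max(coords))


@dataclass
class GenomeModel:
    chromosomes: List[Chromosome]
    islands: Dict[str, np.ndarray]
    genes: List[GeneModel]
    #: moderate-CpG open-sea patches; generator metadata used to position
    #: short hypomethylation events, not part of the island annotation
    open_sea_patches: Dict[str, np.ndarray] = field(default_factory=dict)
    _cpg_cache: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def chrom_sizes(self) -> Dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def cpg_positions(self, chrom: str) -> np.ndarray:
        """0-based positions of the C of every CpG dinucleotide."""
        if chrom not in self._cpg_cache:
            seq = np.frombuffer(self.chromosome(chrom).sequence.encode(), dtype=np.uint8)
            hits = (seq[:-1] == ord("C")) & (seq[1:] == ord("G"))
            self._cpg_cache[chrom] = np.flatnonzero(hits).astype(np.int64)
        return self._cpg_cache[chrom]

    def validate(self) -> None:
        sizes = self.chrom_sizes()
        for chrom, arr in self.islands.items():
            arr = as_interval_array(arr)
            if len(arr) and (arr[0, 0] < 0 or arr[:, 1].max() > sizes[chrom]):
                raise ValueError(f"island outside chromosome bounds on {chrom}")
        for g in self.genes:
            lo, hi = g.span
            if lo < 0 or hi > sizes[g.chrom]:
                raise ValueError(f"gene outside chromosome bounds on {g.chrom}")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=probs)]


def _deplete_cpgs(
    rng: np.random.Generator, seq: np.ndarray, depletion: np.ndarray
) -> None:
    """Erase CpGs in place (G -> T, mimicking deamination) with per-position
    probability ``depletion``."""
    cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
    if len(cg) == 0:
        return
    erase = rng.random(len(cg)) < depletion[cg]
    seq[cg[erase] + 1] = ord("T")


def simulate_genome(config: SimulationConfig) -> GenomeModel:
    """Generate a genome with promoter CpG islands, one gene per slot.

    Raises ``ValueError`` when a chromosome is too short to host the
    requested number of genes.
    """
    config.validate()
    names = config.names()
    n_chroms = len(config.chrom_lengths)

    # distribute genes over chromosomes proportionally to length
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    genes_per_chrom = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    while genes_per_chrom.sum() < config.n_genes:
        genes_per_chrom[int(np.argmax(lengths / (genes_per_chrom + 1)))] += 1

    chromosomes, genes = [], []
    islands: Dict[str, np.ndarray] = {}
    patches: Dict[str, np.ndarray] = {}

    gene_span = config.utr5_length + config.body_length + config.utr3_length
    for ci in range(n_chroms):
        name, length = names[ci], int(config.chrom_lengths[ci])
        n_genes = int(genes_per_chrom[ci])
        if n_genes:
            slot = length // n_genes
            needed = max(
                _MIN_SLOT,
                2 * (gene_span + config.island_halfwidth + config.transition_width)
                + 2 * config.open_sea_patch_length
                + 4000,
            )
            if slot < needed:
                raise ValueError(
                    f"chromosome {name} too short for {n_genes} genes "
                    f"(slot {slot} bp < required {needed} bp)"
                )
        crng = substream(config.seed, "genome", ci)
        seq = _random_sequence(crng, length, config.gc_background)
        depletion = np.full(length, config.background_cpg_depletion)

        isl, pat = [], []
        for gi in range(n_genes):
            slot_start = gi * slot
            center = slot_start + slot // 2
            half = config.island_halfwidth
            island = (center - half, center + half)
            isl.append(island)
            # GC-rich, undepleted island sequence
            seq[island[0] : island[1]] = _random_sequence(
                crng, island[1] - island[0], config.gc_island
            )
            depletion[island[0] : island[1]] = 0.0
            tw = config.transition_width
            depletion[island[0] - tw : island[0]] = config.transition_cpg_depletion
            depletion[island[1] : island[1] + tw] = config.transition_cpg_depletion

            # moderate-CpG open-sea patches: as many as fit between the slot
            # start and the island's upstream transition zone. They carry
            # stable methylated material (capture-visible background), which
            # anchors composition normalization and hosts hypo events.
            patch_limit = center - half - config.transition_width - 1000
            offset = 2000
            n_placed = 0
            while (
                slot_start + offset + config.open_sea_patch_length <= patch_limit
                and n_placed < config.max_patches_per_gene
            ):
                patch = (
                    slot_start + offset,
                    slot_start + offset + config.open_sea_patch_length,
                )
                pat.append(patch)
                depletion[patch[0] : patch[1]] = config.patch_cpg_depletion
                offset += 10_000
                n_placed += 1

            strand = "+" if gi % 2 == 0 else "-"
            tss = center
            if strand == "+":
                utr5 = (tss, tss + config.utr5_length)
                body = (utr5[1], utr5[1] + config.body_length)
                utr3 = (body[1], body[1] + config.utr3_length)
            else:
                utr5 = (tss - config.utr5_length, tss)
                body = (utr5[0] - config.body_length, utr5[0])
                utr3 = (body[0] - config.utr3_length, body[0])
            genes.append(GeneModel(name, strand, tss, utr5, body, utr3))

        _deplete_cpgs(crng, seq, depletion)
        chromosomes.append(Chromosome(name, seq.tobytes().decode()))
        islands[name] = merge_intervals(isl) if isl else np.empty((0, 2), dtype=np.int64)
        patches[name] = as_interval_array(pat) if pat else np.empty((0, 2), dtype=np.int64)

    genome = GenomeModel(chromosomes, islands, genes, patches)
    genome.validate()
    return genome
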