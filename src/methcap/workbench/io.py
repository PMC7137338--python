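"""Format adapters: FASTA, BED, SAM/BAM, TSV tables.

All interval I/O is 0-based half-open (BED semantics). The SAM/BAM adapter
keeps only mapped, primary, non-duplicate records, mirroring de-duplicated
single-end alignments.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from methcap.simdata.capture import FragmentSet
from methcap.simdata.genome import Chromosome, GeneModel, GenomeModel


# -- FASTA ------------------------------------------------------------------

def write_fasta(genome: GenomeModel, path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="")
        for c in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> List[Chromosome]:
    return [
        Chromosome(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# -- BED --------------------------------------------------------------------

def write_bed(intervals_by_chrom: Dict[str, np.ndarray], path, name: str = ".") -> None:
    with open(path, "w") as fh:
        for chrom, arr in intervals_by_chrom.items():
            for start, end in np.asarray(arr):
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (>= 3 columns); validates coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3] if len(fields) > 3 else ".",
                    "score": fields[4] if len(fields) > 4 else ".",
                    "strand": fields[5] if len(fields) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def intervals_from_bed(df: pd.DataFrame) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = sub[["start", "end"]].to_numpy(dtype=np.int64)
        out[chrom] = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    return out


def write_fragments_bed(fragments: FragmentSet, path) -> None:
    """6-column BED, one record per fragment."""
    with open(path, "w") as fh:
        for chrom in fragments.intervals:
            arr = fragments.intervals[chrom]
            strands = fragments.strands.get(chrom)
            for i, (start, end) in enumerate(arr):
                strand = strands[i] if strands is not None and len(strands) else "+"
                fh.write(
                    f"{chrom}\t{int(start)}\t{int(end)}\t{fragments.sample}\t0\t{strand}\n"
                )


def read_fragments_bed(path, sample: str = "", group: str = "") -> FragmentSet:
    df = read_bed(path)
    intervals: Dict[str, np.ndarray] = {}
    strands: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = sub[["start", "end"]].to_numpy(dtype=np.int64)
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        intervals[chrom] = arr[order]
        strands[chrom] = sub["strand"].to_numpy(dtype="U1")[order]
    return FragmentSet(intervals=intervals, strands=strands, sample=sample, group=group)


# -- genes ------------------------------------------------------------------

GENE_COLUMNS = [
    "chrom", "strand", "tss",
    "utr5_start", "utr5_end", "body_start", "body_end", "utr3_start", "utr3_end",
]


def write_genes_tsv(genes: List[GeneModel], path) -> None:
    rows = [
        {
            "chrom": g.chrom, "strand": g.strand, "tss": g.tss,
            "utr5_start": g.utr5[0], "utr5_end": g.utr5[1],
            "body_start": g.body[0], "body_end": g.body[1],
            "utr3_start": g.utr3[0], "utr3_end": g.utr3[1],
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(
            r.chrom, r.strand, int(r.tss),
            (int(r.utr5_start), int(r.utr5_end)),
            (int(r.body_start), int(r.body_end)),
            (int(r.utr3_start), int(r.utr3_end)),
        )
        for r in df.itertuples()
    ]


# -- SAM/BAM ----------------------------------------------------------------

def alignments_to_fragments(path, sample: str = "", group: str = "") -> FragmentSet:
    """Convert SAM/BAM alignments to a FragmentSet: mapped, primary,
    non-duplicate records only."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    intervals: Dict[str, list] = {}
    strands: Dict[str, list] = {}
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                continue
            chrom = rec.reference_name
            intervals.setdefault(chrom, []).append(
                (rec.reference_start, rec.reference_end)
            )
            strands.setdefault(chrom, []).append("-" if rec.is_reverse else "+")
    out_iv, out_st = {}, {}
    for chrom in intervals:
        arr = np.asarray(intervals[chrom], dtype=np.int64)
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        out_iv[chrom] = arr[order]
        out_st[chrom] = np.asarray(strands[chrom], dtype="U1")[order]
    return FragmentSet(intervals=out_iv, strands=out_st, sample=sample, group=group)


# -- TSV tables -------------------------------------------------------------

def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    pd.DataFrame(
        {"chrom": list(sizes), "length": list(sizes.values())}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_chrom_sizes(path) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """DMR table as BED6+: name, -10*log10(simes p) score, '.', then
    n_windows, logFC, simes_p, fdr, direction."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions.itertuples()):
            score = -10.0 * np.log10(max(float(r.simes_p), 1e-300))
            fh.write(
                f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\tregion_{i}\t{score:.2f}\t.\t"
                f"{int(r.n_windows)}\t{float(r.logFC):.4f}\t{float(r.simes_p):.4g}\t"
                f"{float(r.fdr):.4g}\t{r.direction}\n"
            )


def read_regions_bed(path) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "n_windows", "logFC", "simes_p", "fdr", "direction",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bisulfite_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_bisulfite_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "methylated", "total"} - set(df.columns)
    if missing:
        raise ValueError(f"bisulfite table missing columns: {sorted(missing)}")
    if np.any(df["methylated"] > df["total"]):
        raise ValueError("methylated count exceeds total")
    return df
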