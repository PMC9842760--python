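"""Plain-text readers and writers for the pipeline's file formats.

Counts/sample-sheet/TSS/peak-count tables are TSV; sequences are FASTA
(via Bio.SeqIO); peaks are BED6 (0-based, half-open).  TSS tables in 1-based
conventions can be converted on read with ``one_based=True``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import CountMatrix

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = read_counts(counts_path)
    design = read_sample_sheet(samples_path)
    return CountMatrix(counts[list(design.index)], design)


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tss_table(tss: pd.DataFrame, path: str | Path) -> None:
    tss[["gene", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    tss = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss", "strand"}
    if not required <= set(tss.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    if one_based:
        tss = tss.assign(tss=tss["tss"] - 1)
    return tss


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write peaks as BED6; the peak id goes in the name column."""
    bed = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int),
            "end": peaks["end"].astype(int),
            "name": peaks.index,
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    peaks = pd.DataFrame(
        {
            "chrom": bed["chrom"].to_numpy(),
            "start": bed["start"].to_numpy(dtype=int),
            "end": bed["end"].to_numpy(dtype=int),
        },
        index=pd.Index(bed["name"].astype(str).to_numpy(), name="peak"),
    )
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    peaks["summit"] = (peaks["start"] + peaks["end"]) // 2
    return peaks


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
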