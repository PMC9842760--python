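"""ATAC / H3K27ac regulatory-peak integration.

Peaks are 0-based half-open intervals with per-sample tag counts.  The stage
annotates each peak with its signed distance to the nearest transcription
start site (TSS), splits promoter-proximal peaks (|distance| <= 3000 bp,
inclusive) from distal ones, quantifies histone signal in a fixed window
around the peak summit (the 1000-bp window is then "shifted back" — motif
work always uses the original peak intervals), calls differential regions
with the NB Wald machinery from :mod:`isgland.diffexpr`, and hands the
significant regions to motif enrichment.

Distance convention: measured from the peak summit (interval midpoint when no
summit is given) to the TSS, in the gene's frame — negative means upstream of
the gene regardless of its strand.  Ties between equidistant TSSs break to
the lexicographically smaller gene id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import (
    CallThresholds,
    ContrastSpec,
    CountMatrix,
    call_regulated,
    estimate_dispersion,
    size_factors,
    wald_contrast,
)

PROXIMAL_CUTOFF = 3000
WINDOW_HALF_WIDTH = 500

PEAK_COLUMNS = ["chrom", "start", "end", "summit"]


def peak_frame(
    ids: Sequence[str],
    chroms: Sequence[str],
    starts: Sequence[int],
    ends: Sequence[int],
    summits: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Build a validated peak table; summit defaults to the interval midpoint."""
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends},
        index=pd.Index(ids, name="peak"),
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("peaks must satisfy start < end")
    df["summit"] = (
        np.asarray(summits) if summits is not None else (df["start"] + df["end"]) // 2
    )
    return df


def annotate_tss_distance(peaks: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Attach signed distance to the nearest TSS and the nearest gene id.

    ``tss`` needs columns gene, chrom, tss (0-based position), strand.  The
    distance is summit - TSS for plus-strand genes and TSS - summit for
    minus-strand genes, so negative always means upstream of the gene.  Peaks
    on chromosomes absent from the TSS table get NaN distance and are flagged
    ``unannotated`` (excluded by downstream splitting).
    """
    out = peaks.copy()
    out["tss_distance"] = np.nan
    out["nearest_gene"] = pd.NA
    for chrom, group in peaks.groupby("chrom", sort=False):
        sub = tss[tss["chrom"] == chrom]
        if sub.empty:
            continue
        # stable order: position, then gene id, so equidistant ties resolve
        # to the smaller gene id deterministically
        sub = sub.sort_values(["tss", "gene"], kind="stable").reset_index(drop=True)
        pos = sub["tss"].to_numpy()
        summits = group["summit"].to_numpy()
        right = np.searchsorted(pos, summits, side="left")
        left = right - 1
        best_idx = np.empty(summits.size, dtype=int)
        for i, s in enumerate(summits):
            cands = [j for j in (left[i], right[i]) if 0 <= j < pos.size]
            dists = [abs(s - pos[j]) for j in cands]
            dmin = min(dists)
            tied = [j for j, d in zip(cands, dists) if d == dmin]
            best_idx[i] = min(tied, key=lambda j: sub.loc[j, "gene"])
        nearest = sub.loc[best_idx]
        signed = summits - nearest["tss"].to_numpy()
        minus = (nearest["strand"] == "-").to_numpy()
        signed = np.where(minus, -signed, signed)
        out.loc[group.index, "tss_distance"] = signed.astype(float)
        out.loc[group.index, "nearest_gene"] = nearest["gene"].to_numpy()
    out["unannotated"] = out["tss_distance"].isna()
    out["proximal"] = out["tss_distance"].abs() <= PROXIMAL_CUTOFF
    out.loc[out["unannotated"], "proximal"] = False
    return out


def split_proximal_distal(
    peaks: pd.DataFrame, cutoff: int = PROXIMAL_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition annotated peaks at |TSS distance| <= cutoff (inclusive)."""
    if "tss_distance" not in peaks.columns:
        raise ValueError("peaks must be annotated with tss_distance first")
    unannotated = peaks["tss_distance"].isna()
    if unannotated.any() and "unannotated" not in peaks.columns:
        raise ValueError("unannotated peaks present without an exclusion flag")
    annotated = peaks[~unannotated]
    proximal = annotated[annotated["tss_distance"].abs() <= cutoff]
    distal = annotated[annotated["tss_distance"].abs() > cutoff]
    return proximal, distal


def quantify_window(
    peaks: pd.DataFrame,
    signal: Mapping[str, Mapping[str, np.ndarray]],
    half_width: int = WINDOW_HALF_WIDTH,
) -> pd.DataFrame:
    """Sum per-sample signal in [summit - half_width, summit + half_width).

    ``signal`` maps sample id -> chrom -> per-base-pair tag array.  Windows
    running past the chromosome start are truncated and flagged in the
    returned table's ``truncated`` attribute column.
    """
    samples = list(signal)
    out = pd.DataFrame(0.0, index=peaks.index, columns=samples)
    truncated = pd.Series(False, index=peaks.index)
    for peak_id, row in peaks.iterrows():
        lo = int(row["summit"]) - half_width
        hi = int(row["summit"]) + half_width
        if lo < 0:
            truncated[peak_id] = True
            lo = 0
        for sample in samples:
            track = signal[sample].get(row["chrom"])
            if track is None:
                continue
            out.loc[peak_id, sample] = float(track[lo : min(hi, track.size)].sum())
    out["truncated"] = truncated
    return out


@dataclass
class DifferentialPeakResult:
    """Wald results per peak plus the significance rule fold change > 2 and
    padj < 0.05 (both strict), and the scatter table behind the red-point plot."""

    table: pd.DataFrame  # baseMean, log2FC, lfcSE, stat, pvalue, padj, significant, direction
    scatter: pd.DataFrame  # mean normalized tags per condition + fold-change flag
    spec: ContrastSpec


def differential_peaks(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    spec: ContrastSpec,
    fc_min: float = 2.0,
    padj_max: float = 0.05,
) -> DifferentialPeakResult:
    """Differential tag-count analysis of peaks between two conditions.

    Reuses the NB machinery (size factors, MoM dispersion, Wald) on the
    peak x sample table.  Significant <=> |log2FC| > log2(fc_min) and
    padj < padj_max, strict.
    """
    cm = CountMatrix(counts, design)
    factors = size_factors(cm)
    dispersions = estimate_dispersion(cm, factors)
    res = wald_contrast(cm, spec, factors, dispersions)
    lfc_min = float(np.log2(fc_min))
    called = call_regulated(
        res, CallThresholds(lfc_min=lfc_min, padj_max=padj_max, use_adjusted=True)
    )
    called["significant"] = called["up"] | called["down"]
    called["direction"] = np.where(
        called["up"], "up", np.where(called["down"], "down", "none")
    )
    norm = cm.counts / factors
    cond = cm.condition
    scatter = pd.DataFrame(
        {
            spec.denominator: norm.loc[:, cond == spec.denominator].mean(axis=1),
            spec.numerator: norm.loc[:, cond == spec.numerator].mean(axis=1),
        }
    )
    scatter = scatter.loc[res.index]
    scatter["log2FC"] = res["log2FC"]
    scatter["over_fc"] = res["log2FC"].abs() > lfc_min
    return DifferentialPeakResult(table=called, scatter=scatter, spec=spec)


def regions_to_enrichment(
    diff: DifferentialPeakResult,
    direction: str,
    peaks: pd.DataFrame,
    genome: Mapping[str, str],
) -> tuple[dict[str, str], dict[str, str]]:
    """Foreground/background sequences for motif enrichment.

    Foreground: significant peaks in ``direction`` ('up', 'down' or 'any');
    background: all tested peaks.  Sequences come from the original peak
    intervals (not the quantification window), uppercased.
    """
    table = diff.table
    if direction == "any":
        fg_ids = table.index[table["significant"]]
    elif direction in ("up", "down"):
        fg_ids = table.index[table["significant"] & (table["direction"] == direction)]
    else:
        raise ValueError("direction must be 'up', 'down' or 'any'")
    bg_ids = table.index

    def extract(ids) -> dict[str, str]:
        seqs = {}
        for pid in ids:
            row = peaks.loc[pid]
            chrom_seq = genome[row["chrom"]]
            start, end = int(row["start"]), int(row["end"])
            if start < 0 or end > len(chrom_seq):
                raise ValueError(f"peak {pid} outside chromosome bounds")
            seqs[pid] = chrom_seq[start:end].upper()
        return seqs

    return extract(fg_ids), extract(bg_ids)
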