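#!/usr/bin/env python
"""Chromatin-region stage: TSS annotation, proximal exclusion, differential
regions and motif enrichment.

Annotates each simulated peak with its signed nearest-TSS distance, drops
promoter-proximal peaks (|distance| <= 3000 bp), calls differential regions
between the two conditions under the fold-change > 2 and padj < 0.05 rule,
and tests the differential regions for motif enrichment against all tested
regions with the two-tailed hypergeometric test.  Writes tables under
results/peaks/.
"""

from pathlib import Path

from isgland import io as pio
from isgland.diffexpr import ContrastSpec
from isgland.motifs import hypergeometric_enrichment, load_default_motifs, scan_sequences
from isgland.peaks import annotate_tss_distance, differential_peaks, regions_to_enrichment, split_proximal_distal

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "peaks"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    peaks = pio.read_bed(DATA / "peaks.bed")
    tss = pio.read_tss_table(DATA / "peak_tss.tsv")
    counts = pio.read_counts(DATA / "peak_counts.tsv")
    design = pio.read_sample_sheet(DATA / "peak_samples.tsv")
    genome = pio.read_fasta(DATA / "genome.fasta")

    annotated = annotate_tss_distance(peaks, tss)
    proximal, distal = split_proximal_distal(annotated)
    annotated.to_csv(OUT / "peaks_annotated.tsv", sep="\t")
    print(f"{len(annotated)} peaks: {len(proximal)} proximal excluded, "
          f"{len(distal)} distal retained")

    diff = differential_peaks(
        counts.loc[distal.index], design, ContrastSpec("peaks", "KO_IFN", "WT_IFN")
    )
    diff.table.to_csv(OUT / "peaks_diff.tsv", sep="\t")
    diff.scatter.to_csv(OUT / "peaks_scatter.tsv", sep="\t")
    n_sig = int(diff.table["significant"].sum())
    print(f"{n_sig} differential regions (fold change > 2, padj < 0.05)")

    motifs = load_default_motifs()
    fg, bg = regions_to_enrichment(diff, "up", annotated, genome)
    hits = scan_sequences(motifs, bg)
    enrichment = hypergeometric_enrichment(
        list(fg), list(bg), hits, motif_names=sorted(motifs)
    )
    enrichment.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    print(enrichment.sort_values("padj").to_string(index=False))


if __name__ == "__main__":
    main()
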