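#!/usr/bin/env python
"""Generate the synthetic ISG-landscape study.

Simulates the full input set with planted ground truth: a gene x sample NB
count matrix under the 2x2 genotype (WT/KO) x treatment (untreated/IFN)
design, promoter sequences with planted ISRE/GAS/NF-kB instances, a
known-ISG reference list, and ATAC-style peaks with planted differential
regions.  Writes everything as plain text under results/data/.
"""

import argparse
from pathlib import Path

from isgland import io as pio
from isgland.motifs import load_default_motifs
from isgland.simulate import (
    SimConfig,
    simulate_counts,
    simulate_known_isg_reference,
    simulate_peaks,
    simulate_promoters,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    motifs = load_default_motifs()

    counts, design, truth = simulate_counts(cfg)
    promoters, tss, truth = simulate_promoters(cfg, truth, motifs)
    known = simulate_known_isg_reference(truth, 0.43, seed=seed)
    bundle = simulate_peaks(cfg, motifs)

    pio.write_counts(counts, OUT / "counts.tsv")
    pio.write_sample_sheet(design, OUT / "samples.tsv")
    pio.write_fasta(promoters, OUT / "promoters.fasta")
    pio.write_tss_table(tss, OUT / "tss.tsv")
    pio.write_gene_list(known, OUT / "known_isgs.txt")
    pio.write_bed(bundle["peaks"], OUT / "peaks.bed")
    pio.write_counts(bundle["counts"], OUT / "peak_counts.tsv")
    pio.write_sample_sheet(bundle["design"], OUT / "peak_samples.tsv")
    pio.write_fasta(bundle["genome"], OUT / "genome.fasta")
    pio.write_tss_table(bundle["tss"], OUT / "peak_tss.tsv")
    truth.genes.to_csv(OUT / "truth_genes.tsv", sep="\t")
    truth.motifs.to_csv(OUT / "truth_motifs.tsv", sep="\t", index=False)
    bundle["truth"].peaks.to_csv(OUT / "truth_peaks.tsv", sep="\t")

    by_class = truth.genes["class"].value_counts().to_dict()
    print(f"simulated {len(counts)} genes x {counts.shape[1]} samples (seed {seed})")
    print(f"planted classes: {by_class}")
    print(f"known-ISG list: {len(known)} genes; peaks: {len(bundle['peaks'])} "
          f"({int(bundle['truth'].peaks['is_diff'].sum())} differential)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
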