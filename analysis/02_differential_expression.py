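#!/usr/bin/env python
"""NB Wald differential expression for the four canonical contrasts.

Reads the simulated counts and sample sheet, normalises by median-of-ratios,
estimates per-gene NB dispersions by method of moments, and runs the Wald
test for C1 (WT+IFN vs WT), C2 (KO+IFN vs KO), C3 (KO+IFN vs WT+IFN) and
C4 (KO vs WT), calling regulation at padj < 0.05 and |log2FC| > 1.
Writes one result table per contrast under results/de/.
"""

from pathlib import Path

from isgland import io as pio
from isgland.diffexpr import CallThresholds, run_contrasts

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "de"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cm = pio.read_count_matrix(DATA / "counts.tsv", DATA / "samples.tsv")
    results = run_contrasts(cm, thresholds=CallThresholds(lfc_min=1.0, padj_max=0.05))
    for name, res in results.items():
        res.to_csv(OUT / f"{name}.tsv", sep="\t")
        print(f"{name}: {int(res['up'].sum())} up, {int(res['down'].sum())} down "
              f"of {len(res)} tested")


if __name__ == "__main__":
    main()
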