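#!/usr/bin/env python
"""Scan promoter sequences for ISRE, GAS, NF-kB and the TTTC core element.

Scores both strands of every promoter with the bundled motif models at the
default threshold (0.8 x maximum log-odds) and derives the per-gene
ISRE-or-GAS presence flag used to split hidden from non-canonical atypical
ISGs.  Writes the hit table and the presence flags under results/motifs/.
"""

from pathlib import Path

import pandas as pd

from isgland import io as pio
from isgland.motifs import load_default_motifs, motif_presence, scan_sequences

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "motifs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    promoters = pio.read_fasta(DATA / "promoters.fasta")
    motifs = load_default_motifs()
    hits = scan_sequences(motifs, promoters)
    hits.to_csv(OUT / "promoter_hits.tsv", sep="\t", index=False)
    presence = motif_presence(hits, {g: [g] for g in promoters}, ["ISRE", "GAS"])
    presence.astype(int).rename("has_isre_or_stat1").to_csv(
        OUT / "motif_presence.tsv", sep="\t", index_label="gene"
    )
    per_motif = hits["motif"].value_counts().to_dict()
    print(f"{len(hits)} hits over {len(promoters)} promoters: {per_motif}")
    print(f"{int(presence.sum())} promoters carry an ISRE or GAS site")


if __name__ == "__main__":
    main()
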