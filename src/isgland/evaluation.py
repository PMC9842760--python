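"""Planted-truth evaluation scenarios.

Each function runs one benchmark of the pipeline against the synthetic
generator's planted truth and returns plain dictionaries of the measured
quantities: Wald-test calibration under the null, end-to-end class-label
recovery, motif-scan round-trip recovery, and the peak stage's planted
differential-region recovery with motif enrichment.  The analysis drivers,
the test suite and the reproduction script all call these entry points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import classify
from .diffexpr import (
    CallThresholds,
    ContrastSpec,
    CountMatrix,
    run_contrasts,
    build_call_table,
    size_factors,
    wald_contrast,
)
from .motifs import hypergeometric_enrichment, load_default_motifs, motif_presence, scan_sequences
from .peaks import annotate_tss_distance, differential_peaks, regions_to_enrichment, split_proximal_distal
from .simulate import (
    SimConfig,
    simulate_counts,
    simulate_known_isg_reference,
    simulate_peaks,
    simulate_promoters,
)


def type_i_error(
    seed: int,
    n_genes: int = 20_000,
    n_reps: int = 3,
    dispersion: float = 0.1,
    p_cut: float = 0.05,
) -> dict:
    """Fraction of raw Wald p-values below ``p_cut`` in an all-null NB study.

    The statistic is evaluated at the simulation's dispersion, i.e. this
    measures the calibration of the Wald z itself, not of the dispersion
    estimator (see docs/methods.md on small-n method-of-moments estimates).
    """
    cfg = SimConfig(
        n_genes=n_genes, n_reps=n_reps, seed=seed, class_fractions={},
        dispersion=dispersion,
    )
    counts, design, _truth = simulate_counts(cfg)
    cm = CountMatrix(counts, design)
    factors = size_factors(cm)
    disp = pd.Series(dispersion, index=counts.index)
    res = wald_contrast(cm, ContrastSpec.canonical("C1"), factors, disp)
    frac = float((res["pvalue"] < p_cut).mean())
    n = int(len(res))
    return {
        "fraction": frac,
        "n": n,
        "nominal": p_cut,
        "band_3sd": 3 * float(np.sqrt(p_cut * (1 - p_cut) / n)),
    }


def class_recovery(
    seed: int,
    n_genes: int = 2000,
    reported_fraction: float = 0.43,
    thresholds: CallThresholds | None = None,
) -> dict:
    """End-to-end typical/atypical recovery against the planted truth.

    Runs the full chain — simulate, four Wald contrasts, promoter scan,
    taxonomy — and scores sensitivity and precision of the typical and
    atypical labels, plus the subdivision of atypical genes.
    """
    cfg = SimConfig(n_genes=n_genes, seed=seed)
    counts, design, truth = simulate_counts(cfg)
    motif_set = load_default_motifs()
    promoters, _tss, truth = simulate_promoters(cfg, truth, motif_set)
    known = simulate_known_isg_reference(truth, reported_fraction, seed=seed)

    cm = CountMatrix(counts, design)
    results = run_contrasts(cm, thresholds=thresholds or CallThresholds())
    calls = build_call_table(results, genes=list(counts.index))
    hits = scan_sequences(motif_set, promoters)
    presence = motif_presence(hits, {g: [g] for g in counts.index}, ["ISRE", "GAS"])
    classification = classify(calls, known, presence)

    expected = truth.genes["expected_label"]
    out: dict = {"n_genes": n_genes}
    for label in ("typical", "atypical"):
        predicted = classification["label"] == label
        actual = expected == label
        tp = int((predicted & actual).sum())
        out[f"{label}_sensitivity"] = tp / max(int(actual.sum()), 1)
        out[f"{label}_precision"] = tp / max(int(predicted.sum()), 1)
        out[f"{label}_planted"] = int(actual.sum())
        out[f"{label}_called"] = int(predicted.sum())
    sub_expected = truth.genes["expected_sublabel"]
    both = classification["sublabel"].notna() & sub_expected.notna()
    out["sublabel_agreement"] = float(
        (classification.loc[both, "sublabel"] == sub_expected[both]).mean()
    ) if int(both.sum()) else float("nan")
    return out


def motif_roundtrip(seed: int, n_genes: int = 300) -> dict:
    """Plant every motif at rate 1 and recover instances with the scanner.

    Recovery counts a planted instance as found when a hit with the same
    motif, start and strand is reported for that promoter at the default
    score threshold; background hits elsewhere are allowed.
    """
    motif_set = load_default_motifs()
    cfg = SimConfig(
        n_genes=n_genes,
        seed=seed,
        class_fractions={"typical": 1.0},
        motif_plant_rate_by_class={
            "typical": {"ISRE": 1.0, "GAS": 1.0, "NFKB": 1.0, "IRE": 1.0}
        },
    )
    _counts, _design, truth = simulate_counts(cfg)
    promoters, _tss, truth = simulate_promoters(cfg, truth, motif_set)
    hits = scan_sequences(motif_set, promoters)
    hit_keys = set(map(tuple, hits[["seq_id", "motif", "start", "strand"]].to_numpy()))
    planted = truth.motifs
    found = sum(
        (row.gene, row.motif, row.start, row.strand) in hit_keys
        for row in planted.itertuples()
    )
    return {
        "planted": int(len(planted)),
        "recovered": int(found),
        "recovery": found / len(planted),
    }


def nearest_tss_bruteforce_agreement(seed: int, n_peaks: int = 1000, n_tss: int = 60) -> dict:
    """Agreement of the nearest-TSS annotation with exhaustive minimisation."""
    rng = np.random.default_rng([seed, 5])
    summits = rng.integers(500, 2_000_000, n_peaks)
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": summits - 100,
            "end": summits + 100,
            "summit": summits,
        },
        index=pd.Index([f"p{i}" for i in range(n_peaks)], name="peak"),
    )
    tss = pd.DataFrame(
        {
            "gene": [f"g{i:03d}" for i in range(n_tss)],
            "chrom": "chr1",
            "tss": rng.integers(0, 2_000_000, n_tss),
            "strand": rng.choice(["+", "-"], n_tss),
        }
    )
    out = annotate_tss_distance(peaks, tss)
    agree = 0
    pos = tss["tss"].to_numpy()
    for pid, row in out.iterrows():
        s = int(peaks.loc[pid, "summit"])
        dists = np.abs(pos - s)
        best = dists.min()
        tied = sorted(tss.loc[dists == best, "gene"])
        agree += row["nearest_gene"] == tied[0] and abs(row["tss_distance"]) == best
    return {"n": n_peaks, "agreement": agree / n_peaks}


def peak_recovery(seed: int, n_peaks: int = 2000) -> dict:
    """Planted differential-peak recovery and motif enrichment ranking.

    Simulates peaks (true fold change 4, dispersion 0.05, duplicates),
    annotates TSS distances, drops promoter-proximal peaks, calls
    differential regions under the fold-change-2 / padj-0.05 rule and runs
    the two-tailed hypergeometric enrichment on the up-regulated regions.
    """
    cfg = SimConfig(n_peaks=n_peaks, seed=seed)
    motif_set = load_default_motifs()
    bundle = simulate_peaks(cfg, motif_set)
    annotated = annotate_tss_distance(bundle["peaks"], bundle["tss"])
    proximal, distal = split_proximal_distal(annotated)
    conserved = len(proximal) + len(distal) == len(annotated)

    cond_a, cond_b = cfg.peak_conditions
    diff = differential_peaks(
        bundle["counts"].loc[distal.index],
        bundle["design"],
        ContrastSpec("peaks", cond_b, cond_a),
    )
    truth = bundle["truth"].peaks
    planted = truth.index[truth["is_diff"]].intersection(distal.index)
    called_up = diff.table.index[diff.table["significant"] & (diff.table["direction"] == "up")]
    recovery = len(planted.intersection(called_up)) / max(len(planted), 1)

    fg, bg = regions_to_enrichment(diff, "up", annotated, bundle["genome"])
    peak_hits = scan_sequences(motif_set, bg)
    enrichment = hypergeometric_enrichment(
        list(fg), list(bg), peak_hits, motif_names=sorted(motif_set)
    )
    ranked = enrichment.sort_values("padj")
    return {
        "n_peaks": n_peaks,
        "partition_conserved": bool(conserved),
        "n_proximal": int(len(proximal)),
        "n_distal": int(len(distal)),
        "planted_differential_distal": int(len(planted)),
        "recovered": int(len(planted.intersection(called_up))),
        "recovery": float(recovery),
        "top_enriched_motif": str(ranked["motif"].iloc[0]),
        "enrichment": enrichment,
    }
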