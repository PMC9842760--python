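"""End-to-end orchestration of the synthetic ISG-landscape analysis.

``run_pipeline`` executes: simulate -> differential expression (C1-C4) ->
ISG classification -> promoter motif scan -> peak annotation/differential
calling -> motif enrichment of differential regions -> report.  Every stage
writes plain-text outputs into the run directory and the manifest records a
content hash per file, so a run is reproducible from its manifest inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as pio
from .classify import classify, write_report
from .diffexpr import (
    CallThresholds,
    ContrastSpec,
    CountMatrix,
    build_call_table,
    run_contrasts,
)
from .motifs import hypergeometric_enrichment, load_default_motifs, motif_presence, scan_sequences
from .peaks import annotate_tss_distance, differential_peaks, regions_to_enrichment, split_proximal_distal
from .simulate import (
    PlantedTruth,
    SimConfig,
    simulate_counts,
    simulate_known_isg_reference,
    simulate_peaks,
    simulate_promoters,
)

log = logging.getLogger("isgland")

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": {},  # SimConfig field overrides
    "de": {"lfc_min": 1.0, "padj_max": 0.05, "use_adjusted": True, "p_max": None},
    "classify": {"reported_fraction": 0.43},
    "peaks": {"fc_min": 2.0, "padj_max": 0.05, "proximal_cutoff": 3000},
    "enrich": {"direction": "up", "alternative": "two-tailed"},
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section: {section!r}")
            cfg[section].update(values or {})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Context manager logging one pipeline stage's wall time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.1fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
        return False


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None,
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run the full synthetic analysis; returns the report dictionary."""
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = {k: dict(DEFAULT_CONFIG[k]) for k in DEFAULT_CONFIG}
        for section, values in config.items():
            cfg[section].update(values or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(*args, path)
        written.append(path)
        return path

    sim_kwargs = dict(cfg["simulate"])
    if seed is not None:
        sim_kwargs["seed"] = int(seed)
    sim = SimConfig(**sim_kwargs)
    motif_set = load_default_motifs()

    try:
        with _Stage("simulate"):
            counts, design, truth = simulate_counts(sim)
            promoters, tss, truth = simulate_promoters(sim, truth, motif_set)
            known = simulate_known_isg_reference(
                truth, cfg["classify"]["reported_fraction"], seed=sim.seed
            )
            peak_bundle = simulate_peaks(sim, motif_set)
            save("counts.tsv", pio.write_counts, counts)
            save("samples.tsv", pio.write_sample_sheet, design)
            save("promoters.fasta", pio.write_fasta, promoters)
            save("tss.tsv", pio.write_tss_table, tss)
            save("known_isgs.txt", pio.write_gene_list, known)
            save("peaks.bed", pio.write_bed, peak_bundle["peaks"])
            save("peak_counts.tsv", pio.write_counts, peak_bundle["counts"])
            save("peak_samples.tsv", pio.write_sample_sheet, peak_bundle["design"])
            save("truth_genes.tsv", lambda df, p: df.to_csv(p, sep="\t"), truth.genes)
            save(
                "truth_peaks.tsv",
                lambda df, p: df.to_csv(p, sep="\t"),
                peak_bundle["truth"].peaks,
            )

        with _Stage("de"):
            de_cfg = cfg["de"]
            thresholds = CallThresholds(
                lfc_min=de_cfg["lfc_min"],
                p_max=de_cfg.get("p_max"),
                padj_max=de_cfg.get("padj_max"),
                use_adjusted=de_cfg.get("use_adjusted", True),
            )
            cm = CountMatrix(counts, design)
            results = run_contrasts(cm, thresholds=thresholds)
            for name, res in results.items():
                save(f"de_{name}.tsv", lambda df, p: df.to_csv(p, sep="\t"), res)

        with _Stage("scan"):
            hits = scan_sequences(motif_set, promoters)
            save("promoter_hits.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), hits)
            presence = motif_presence(
                hits, {g: [g] for g in counts.index}, ["ISRE", "GAS"]
            )

        with _Stage("classify"):
            calls = build_call_table(results, genes=list(counts.index))
            classification = classify(calls, known, presence)
            summary = write_report(
                classification, outdir / "classification.tsv", outdir / "classification.json"
            )
            written += [outdir / "classification.tsv", outdir / "classification.json"]

        with _Stage("peaks"):
            pk_cfg = cfg["peaks"]
            annotated = annotate_tss_distance(peak_bundle["peaks"], peak_bundle["tss"])
            proximal, distal = split_proximal_distal(
                annotated, cutoff=pk_cfg["proximal_cutoff"]
            )
            cond_a, cond_b = sim.peak_conditions
            diff = differential_peaks(
                peak_bundle["counts"].loc[distal.index],
                peak_bundle["design"],
                ContrastSpec("peaks", cond_b, cond_a),
                fc_min=pk_cfg["fc_min"],
                padj_max=pk_cfg["padj_max"],
            )
            save("peaks_annotated.tsv", lambda df, p: df.to_csv(p, sep="\t"), annotated)
            save("peaks_diff.tsv", lambda df, p: df.to_csv(p, sep="\t"), diff.table)
            save("peaks_scatter.tsv", lambda df, p: df.to_csv(p, sep="\t"), diff.scatter)

        with _Stage("enrich"):
            en_cfg = cfg["enrich"]
            fg, bg = regions_to_enrichment(
                diff, en_cfg["direction"], annotated, peak_bundle["genome"]
            )
            if fg:
                peak_hits = scan_sequences(motif_set, bg)
                enrichment = hypergeometric_enrichment(
                    list(fg),
                    list(bg),
                    peak_hits,
                    motif_names=sorted(motif_set),
                    alternative=en_cfg["alternative"],
                )
            else:
                log.warning("no significant peaks in direction %s; enrichment skipped", en_cfg["direction"])
                enrichment = pd.DataFrame(
                    columns=["motif", "k", "n", "K", "N", "fold_enrichment", "pvalue", "padj"]
                )
            save("enrichment.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), enrichment)

        with _Stage("report"):
            report = {
                "seed": sim.seed,
                "parameters": {
                    "simulate": {k: v for k, v in sim_kwargs.items()},
                    "de": de_cfg,
                    "classify": cfg["classify"],
                    "peaks": pk_cfg,
                    "enrich": en_cfg,
                },
                "classification": summary,
                "peaks": {
                    "n_total": int(len(annotated)),
                    "n_proximal": int(len(proximal)),
                    "n_distal": int(len(distal)),
                    "n_significant": int(diff.table["significant"].sum()),
                },
                "enrichment": enrichment.to_dict(orient="records"),
            }
            report_path = outdir / "report.json"
            with open(report_path, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            written.append(report_path)
            manifest = {
                "seed": sim.seed,
                "parameters": report["parameters"],
                "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
            }
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
    except Exception:
        (outdir / "failed").write_text("pipeline aborted; see logs\n")
        raise
    return report
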