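"""Synthetic data with planted ground truth for the ISG-landscape pipeline.

Generates every input the pipeline consumes — an NB count matrix under the
2x2 genotype x interferon factorial, promoter sequences with planted motif
instances, a known-ISG reference list, and peak tag counts with planted
differential regions — together with a truth record per gene/peak, so each
downstream stage can be scored against what was planted.

Gene classes and their mean model (log2 effects added on top of a
log-uniform baseline, multiplied by per-sample library size factors):

* ``typical``               +lfc_typical under IFN in both genotypes
* ``atypical_hidden``       +lfc_atypical under IFN in the KO only; promoter
                            carries an ISRE (the "hidden" signature)
* ``atypical_noncanonical`` +lfc_atypical under IFN in the KO only; promoter
                            carries no ISRE/GAS (optionally NF-kB)
* ``constitutive``          +lfc_constitutive in the KO at baseline (both
                            treatments) — exercises the cluster veto logic
* ``null``                  no effect

Counts are NB with variance mu + alpha * mu^2 (dispersion alpha), the exact
parameterisation assumed by the differential-expression stage, so parameter
recovery tests are self-consistent.  ``dispersion = 0`` degenerates to
Poisson.  Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import GENOTYPES, TREATMENTS
from .motifs import Motif, load_default_motifs, reverse_complement

GENE_CLASSES = (
    "typical",
    "atypical_hidden",
    "atypical_noncanonical",
    "constitutive",
    "null",
)
ATYPICAL_CLASSES = ("atypical_hidden", "atypical_noncanonical")

# Default planted-class mix: typical-to-atypical ratio mirrors the observed
# ISG landscape (~448 typical vs ~605 atypical genes) with ~20% of genes
# responsive overall; the remainder are null.
_DEFAULT_FRACTIONS = {
    "typical": 0.07,
    "atypical_hidden": 0.055,
    "atypical_noncanonical": 0.04,
    "constitutive": 0.04,
}

# Per-class probability of planting one instance of each motif type.
# Non-canonical atypical genes must never receive ISRE/GAS (their defining
# property); null promoters get a little NF-kB background so motif presence
# is not trivially class-separating.
_DEFAULT_PLANT_RATES: dict[str, dict[str, float]] = {
    "typical": {"ISRE": 0.9},
    "atypical_hidden": {"ISRE": 1.0},
    "atypical_noncanonical": {"NFKB": 0.5},
    "constitutive": {},
    "null": {"NFKB": 0.1},
}


@dataclass
class SimConfig:
    """Scenario parameters for the synthetic study."""

    n_genes: int = 2000
    n_reps: int = 3
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    lfc_typical: float = 2.0
    lfc_atypical: float = 2.0
    lfc_constitutive: float = 1.5
    dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    library_size_factors: Sequence[float] | None = None  # drawn log-normal if None
    library_size_sigma: float = 0.2
    seed: int = 0
    promoter_length: int = 1000
    motif_plant_rate_by_class: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PLANT_RATES.items()}
    )
    # peak simulation
    n_peaks: int = 2000
    peak_diff_fraction: float = 0.15
    tss_distance_range: tuple[int, int] = (-20000, 20000)
    peak_fc: float = 4.0
    peak_dispersion: float = 0.05
    peak_n_reps: int = 2
    peak_width: int = 200
    peak_baseline_range: tuple[float, float] = (50.0, 500.0)
    peak_conditions: tuple[str, str] = ("WT_IFN", "KO_IFN")
    peak_motif: str = "ISRE"

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_reps <= 0:
            raise ValueError("n_genes and n_reps must be positive")
        fracs = dict(self.class_fractions)
        unknown = set(fracs) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if any(f < 0 for f in fracs.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(fracs.values()) > 1 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        if self.dispersion < 0 or self.peak_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_mean_range must be positive and ordered")
        rates = self.motif_plant_rate_by_class.get("atypical_noncanonical", {})
        if any(rates.get(m, 0) > 0 for m in ("ISRE", "GAS")):
            raise ValueError(
                "atypical_noncanonical promoters must not plant ISRE or GAS"
            )

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedTruth:
    """Planted per-gene (and per-peak) ground truth."""

    genes: pd.DataFrame  # class, true lfc per contrast, reported flag, expected label
    motifs: pd.DataFrame | None = None  # gene, motif, start, strand
    peaks: pd.DataFrame | None = None  # is_diff, true_fc, tss_distance, nearest gene


def _assign_classes(config: SimConfig) -> pd.Series:
    """Deterministic class assignment by fraction (largest blocks first)."""
    n = config.n_genes
    counts = {
        cls: int(round(config.class_fractions.get(cls, 0.0) * n))
        for cls in GENE_CLASSES
        if cls != "null"
    }
    total = sum(counts.values())
    if total > n:
        raise ValueError("class fractions allocate more genes than n_genes")
    labels = []
    for cls in GENE_CLASSES:
        if cls != "null":
            labels += [cls] * counts[cls]
    labels += ["null"] * (n - total)
    genes = [f"g{i + 1:05d}" for i in range(n)]
    return pd.Series(labels, index=pd.Index(genes, name="gene"), name="class")


def _true_effects(cls: str, config: SimConfig) -> dict[str, float]:
    """True log2 effects for the four canonical contrasts."""
    if cls == "typical":
        return {"C1": config.lfc_typical, "C2": config.lfc_typical, "C3": 0.0, "C4": 0.0}
    if cls in ATYPICAL_CLASSES:
        return {"C1": 0.0, "C2": config.lfc_atypical, "C3": config.lfc_atypical, "C4": 0.0}
    if cls == "constitutive":
        e = config.lfc_constitutive
        return {"C1": 0.0, "C2": 0.0, "C3": e, "C4": e}
    return {"C1": 0.0, "C2": 0.0, "C3": 0.0, "C4": 0.0}


def _condition_effect(cls: str, genotype: str, treatment: str, config: SimConfig) -> float:
    """log2 shift of the mean in one design cell, relative to WT untreated."""
    e = 0.0
    if cls == "typical" and treatment == "IFN":
        e += config.lfc_typical
    if cls in ATYPICAL_CLASSES and genotype == "KO" and treatment == "IFN":
        e += config.lfc_atypical
    if cls == "constitutive" and genotype == "KO":
        e += config.lfc_constitutive
    return e


def nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB counts with variance mean + dispersion * mean^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=mean.shape)


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate the gene x sample count matrix and its sample sheet.

    Returns (counts, sample_sheet, truth); the sample sheet has columns
    genotype, treatment, replicate and is indexed by sample id.
    """
    rng = config.rng(stream=1)
    classes = _assign_classes(config)
    genes = classes.index
    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))

    samples, meta = [], []
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            for rep in range(1, config.n_reps + 1):
                samples.append(f"{genotype}_{treatment}_{rep}")
                meta.append((genotype, treatment, rep))
    design = pd.DataFrame(
        meta, index=pd.Index(samples, name="sample"),
        columns=["genotype", "treatment", "replicate"],
    )
    if config.library_size_factors is not None:
        sf = np.asarray(config.library_size_factors, dtype=float)
        if sf.size != len(samples) or (sf <= 0).any():
            raise ValueError("library_size_factors must be positive, one per sample")
    else:
        sf = np.exp(rng.normal(0.0, config.library_size_sigma, size=len(samples)))
        sf /= np.exp(np.mean(np.log(sf)))

    effects = np.zeros((len(genes), len(samples)))
    for j, (genotype, treatment, _rep) in enumerate(meta):
        effects[:, j] = [
            _condition_effect(cls, genotype, treatment, config) for cls in classes
        ]
    mean = baseline[:, None] * sf[None, :] * 2.0 ** effects
    counts = pd.DataFrame(
        nb_draw(rng, mean, config.dispersion), index=genes, columns=samples
    )

    truth_genes = pd.DataFrame({"class": classes})
    for contrast in ("C1", "C2", "C3", "C4"):
        truth_genes[f"true_lfc_{contrast}"] = [
            _true_effects(cls, config)[contrast] for cls in classes
        ]
    truth_genes["baseline_mean"] = baseline
    truth_genes["reported"] = False
    return counts, design, PlantedTruth(genes=truth_genes)


def simulate_promoters(
    config: SimConfig,
    truth: PlantedTruth,
    motif_set: Mapping[str, Motif] | None = None,
) -> tuple[dict[str, str], pd.DataFrame, PlantedTruth]:
    """Random background promoters with motif consensus instances planted.

    Background is i.i.d. uniform A/C/G/T.  Each gene's class determines the
    per-motif plant probability; a planted instance is the motif's consensus
    (or its reverse complement, strand chosen at random) at a random
    non-overlapping position, recorded in the truth.  Also emits a TSS table
    placing every promoter upstream of its gene on a virtual chromosome.

    Returns (sequences by gene, tss_table, truth-with-motifs).
    """
    motif_set = motif_set or load_default_motifs()
    L = config.promoter_length
    max_len = max(m.length for m in motif_set.values())
    if L < max_len:
        raise ValueError(f"promoter_length {L} shorter than longest motif ({max_len})")
    rng = config.rng(stream=2)
    seqs: dict[str, str] = {}
    planted_rows = []
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for gene, cls in truth.genes["class"].items():
        seq = rng.integers(0, 4, size=L)
        rates = config.motif_plant_rate_by_class.get(cls, {})
        occupied: list[tuple[int, int]] = []
        for motif_name in sorted(rates):
            if rng.random() >= rates[motif_name]:
                continue
            motif = motif_set[motif_name]
            site = motif.consensus
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else reverse_complement(site)
            for _attempt in range(100):
                start = int(rng.integers(0, L - len(site) + 1))
                span = (start, start + len(site))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    break
            else:  # pragma: no cover - pathological crowding
                continue
            occupied.append(span)
            seq[span[0] : span[1]] = ["ACGT".index(c) for c in inserted]
            planted_rows.append((gene, motif_name, start, strand))
        seqs[gene] = lut[seq].tobytes().decode("ascii")
    planted = pd.DataFrame(
        planted_rows, columns=["gene", "motif", "start", "strand"]
    )
    genes = list(truth.genes.index)
    tss_table = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chrSim",
            "tss": [5000 + 10000 * i for i in range(len(genes))],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(len(genes))],
        }
    )
    new_truth = PlantedTruth(genes=truth.genes, motifs=planted, peaks=truth.peaks)
    return seqs, tss_table, new_truth


def simulate_known_isg_reference(
    truth: PlantedTruth, reported_fraction: float, seed: int = 0
) -> list[str]:
    """Known-ISG reference list: all typical genes plus a random
    ``reported_fraction`` of the planted atypical genes (marked ``reported``
    in the truth — those genes are expected to classify as reported rather
    than hidden/noncanonical)."""
    if not 0 <= reported_fraction <= 1:
        raise ValueError("reported_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    genes = truth.genes
    typical = list(genes.index[genes["class"] == "typical"])
    atypical = list(genes.index[genes["class"].isin(ATYPICAL_CLASSES)])
    reported = [g for g in atypical if rng.random() < reported_fraction]
    genes.loc[:, "reported"] = False
    genes.loc[reported, "reported"] = True
    expected = pd.Series("none", index=genes.index, dtype="object")
    expected[genes["class"] == "typical"] = "typical"
    expected[genes["class"].isin(ATYPICAL_CLASSES)] = "atypical"
    genes["expected_label"] = expected
    sub = pd.Series(pd.NA, index=genes.index, dtype="object")
    sub[genes["class"] == "atypical_hidden"] = "hidden"
    sub[genes["class"] == "atypical_noncanonical"] = "noncanonical"
    sub[genes["reported"]] = "reported"
    genes["expected_sublabel"] = sub
    return sorted(typical + reported)


def simulate_peaks(
    config: SimConfig,
    motif_set: Mapping[str, Motif] | None = None,
) -> dict:
    """Peak intervals at known TSS distances with NB tag counts.

    Places TSSs every 50 kb on one synthetic chromosome, draws each peak's
    signed TSS distance uniformly from ``tss_distance_range`` (gene-strand
    frame), and gives a ``peak_diff_fraction`` subset a true fold change of
    ``peak_fc`` in the second condition of ``peak_conditions``.  The genome
    sequence is uniform-random background with the ``peak_motif`` consensus
    planted at the summit of every true-differential peak, so motif
    enrichment has a planted positive.

    Returns a dict with peaks, counts, design, tss, genome ({chrom: seq}),
    and truth (a PlantedTruth with the ``peaks`` table filled).
    """
    motif_set = motif_set or load_default_motifs()
    rng = config.rng(stream=4)
    n = config.n_peaks
    lo, hi = config.tss_distance_range
    spacing = 50000
    n_tss = max(2, n // 3)
    chrom = "chrP"
    chrom_len = (n_tss + 1) * spacing
    tss = pd.DataFrame(
        {
            "gene": [f"pg{i + 1:05d}" for i in range(n_tss)],
            "chrom": chrom,
            "tss": [spacing // 2 + spacing * i for i in range(n_tss)],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(n_tss)],
        }
    )
    tss_idx = rng.integers(0, n_tss, size=n)
    dist = rng.integers(lo, hi + 1, size=n)
    strands = tss["strand"].to_numpy()[tss_idx]
    tss_pos = tss["tss"].to_numpy()[tss_idx]
    summit = np.where(strands == "+", tss_pos + dist, tss_pos - dist)
    half = config.peak_width // 2
    start = np.clip(summit - half, 0, chrom_len - config.peak_width)
    end = start + config.peak_width
    summit = start + half
    ids = [f"peak{i + 1:05d}" for i in range(n)]
    peaks = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": end, "summit": summit},
        index=pd.Index(ids, name="peak"),
    )

    n_diff = int(round(config.peak_diff_fraction * n))
    is_diff = np.zeros(n, dtype=bool)
    is_diff[rng.choice(n, size=n_diff, replace=False)] = True

    cond_a, cond_b = config.peak_conditions
    samples, cond = [], []
    for c in (cond_a, cond_b):
        for rep in range(1, config.peak_n_reps + 1):
            samples.append(f"{c}_{rep}")
            cond.append(c)
    genotype = [c.rsplit("_", 1)[0] for c in cond]
    treatment = [c.rsplit("_", 1)[1] for c in cond]
    design = pd.DataFrame(
        {
            "genotype": genotype,
            "treatment": treatment,
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    b_lo, b_hi = config.peak_baseline_range
    baseline = np.exp(rng.uniform(np.log(b_lo), np.log(b_hi), size=n))
    mean = np.tile(baseline[:, None], (1, len(samples)))
    in_b = np.array([c == cond_b for c in cond])
    mean[np.ix_(is_diff, in_b)] *= config.peak_fc
    counts = pd.DataFrame(
        nb_draw(rng, mean, config.peak_dispersion), index=peaks.index, columns=samples
    )

    genome_arr = rng.integers(0, 4, size=chrom_len).astype(np.uint8)
    site = motif_set[config.peak_motif].consensus
    site_codes = np.array([("ACGT").index(c) for c in site], dtype=np.uint8)
    for i in np.nonzero(is_diff)[0]:
        s = int(summit[i]) - len(site) // 2
        genome_arr[s : s + len(site)] = site_codes
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {chrom: lut[genome_arr].tobytes().decode("ascii")}

    truth_peaks = pd.DataFrame(
        {
            "is_diff": is_diff,
            "true_fc": np.where(is_diff, config.peak_fc, 1.0),
            "tss_distance": dist,
            "gene": tss["gene"].to_numpy()[tss_idx],
        },
        index=peaks.index,
    )
    return {
        "peaks": peaks,
        "counts": counts,
        "design": design,
        "tss": tss,
        "genome": genome,
        "truth": PlantedTruth(genes=pd.DataFrame(), peaks=truth_peaks),
    }
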