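"""Negative-binomial Wald differential expression for a 2x2 factorial design.

The model is deliberately simple and fully self-contained: median-of-ratios
library normalisation, per-gene method-of-moments dispersion (variance =
mu + alpha * mu^2), and a delta-method Wald test on the log2 ratio of
normalised group means.  This is the test *family* used by standard RNA-seq
DE tools, without their dispersion-trend shrinkage, LFC shrinkage or
independent filtering — see docs/methods.md for the consequences, in
particular for small replicate numbers.

Conditions are named ``<genotype>_<treatment>`` (e.g. ``WT_IFN``); the four
canonical contrasts of the genotype x interferon design are:

    C1  WT_IFN  vs WT_untreated
    C2  KO_IFN  vs KO_untreated
    C3  KO_IFN  vs WT_IFN
    C4  KO_untreated vs WT_untreated
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8
PSEUDO_MEAN = 0.5

GENOTYPES = ("WT", "KO")
TREATMENTS = ("untreated", "IFN")

#: canonical contrast name -> (numerator condition, denominator condition)
CANONICAL_CONTRASTS: dict[str, tuple[str, str]] = {
    "C1": ("WT_IFN", "WT_untreated"),
    "C2": ("KO_IFN", "KO_untreated"),
    "C3": ("KO_IFN", "WT_IFN"),
    "C4": ("KO_untreated", "WT_untreated"),
}


@dataclass
class CountMatrix:
    """Gene x sample integer counts with factorial sample metadata.

    ``counts``: DataFrame, rows indexed by gene id, columns by sample id.
    ``design``: DataFrame indexed by sample id with ``genotype`` and
    ``treatment`` columns.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("sample order in counts and design must match")
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer) and not np.allclose(
            vals, np.round(vals)
        ):
            raise ValueError("counts must be integers")
        for col in ("genotype", "treatment"):
            if col not in self.design.columns:
                raise ValueError(f"design lacks required column {col!r}")
        bad_g = set(self.design["genotype"]) - set(GENOTYPES)
        bad_t = set(self.design["treatment"]) - set(TREATMENTS)
        if bad_g or bad_t:
            raise ValueError(f"unknown design levels: {bad_g | bad_t}")

    @property
    def condition(self) -> pd.Series:
        return self.design["genotype"] + "_" + self.design["treatment"]

    def samples_in(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise condition contrast (numerator over denominator)."""

    name: str
    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator must differ")

    @classmethod
    def canonical(cls, name: str) -> "ContrastSpec":
        num, den = CANONICAL_CONTRASTS[name]
        return cls(name, num, den)

    def swapped(self) -> "ContrastSpec":
        return ContrastSpec(self.name + "_swapped", self.denominator, self.numerator)


@dataclass(frozen=True)
class CallThresholds:
    """Regulation-call thresholds; strict inequalities throughout.

    ``use_adjusted`` selects whether the p criterion reads the BH-adjusted or
    the raw p-value.  The volcano/heatmap style calls use raw p < 0.005 with
    log2FC > 0.5 or > 1; the classifier default is padj < 0.05, log2FC > 1.
    """

    lfc_min: float = 1.0
    p_max: float | None = None
    padj_max: float | None = 0.05
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.use_adjusted and self.padj_max is None:
            raise ValueError("padj_max required when use_adjusted")
        if not self.use_adjusted and self.p_max is None:
            raise ValueError("p_max required when not use_adjusted")


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with a nonzero count in every sample; each
    sample's factor is the median over reference genes of count / per-gene
    geometric mean.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.to_numpy(dtype=float)
    usable = (vals > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; supply a pseudo-reference "
            "or filter samples"
        )
    logs = np.log(vals[usable])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def estimate_dispersion(
    counts: CountMatrix,
    factors: pd.Series,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion, pooled across conditions.

    Within each condition with >= 2 replicates the moment estimate is
    alpha_c = (variance_c - mean_c) / mean_c^2 on size-factor-normalised
    counts; estimates are pooled across conditions with (n_c - 1) weights and
    clipped at the floor.  Computing the moments per condition (rather than
    against the grand mean) keeps the estimator unbiased for genes whose
    condition means genuinely differ.  Genes whose normalised counts are
    Poisson-like or constant clip to the floor; all-zero genes get the floor.
    """
    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()
    cond = counts.condition.to_numpy()
    weighted = np.zeros(norm.shape[0])
    df = 0
    for c in np.unique(cond):
        cols = cond == c
        n_c = int(cols.sum())
        if n_c >= 2:
            v = norm[:, cols].var(axis=1, ddof=1)
            m = norm[:, cols].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(m > 0, (v - m) / m**2, 0.0)
            weighted += (n_c - 1) * a
            df += n_c - 1
    if df == 0:
        raise ValueError("dispersion estimation needs >= 2 replicates in some condition")
    alpha = np.maximum(weighted / df, floor)
    return pd.Series(alpha, index=counts.counts.index, name="dispersion")


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def wald_contrast(
    counts: CountMatrix,
    spec: ContrastSpec,
    factors: pd.Series,
    dispersions: pd.Series,
    pseudo_mean: float = PSEUDO_MEAN,
) -> pd.DataFrame:
    """NB Wald test of one condition against another.

    log2FC is computed on size-factor-normalised group means with a pseudo
    mean ``c`` added to both: log2((m_num + c) / (m_den + c)).  Its standard
    error follows from the delta method under the NB variance function:

        se^2 = (1/ln 2)^2 * sum_groups (mu_g + alpha mu_g^2) / (n_g mu_g^2)

    with mu_g the (pseudo-shifted) group mean.  Genes with zero counts in all
    samples of both groups are excluded from testing and from the BH family.

    Returns a DataFrame (index = tested genes) with columns baseMean, log2FC,
    lfcSE, stat, pvalue, padj.
    """
    num_samples = counts.samples_in(spec.numerator)
    den_samples = counts.samples_in(spec.denominator)
    if not num_samples or not den_samples:
        raise ValueError(
            f"contrast {spec.name}: empty condition "
            f"({spec.numerator}: {len(num_samples)}, {spec.denominator}: {len(den_samples)})"
        )
    norm = counts.counts / factors
    num = norm[num_samples].to_numpy()
    den = norm[den_samples].to_numpy()
    tested = (num.sum(axis=1) + den.sum(axis=1)) > 0
    num, den = num[tested], den[tested]
    alpha = dispersions.loc[counts.counts.index[tested]].to_numpy()

    n1, n2 = num.shape[1], den.shape[1]
    m1 = num.mean(axis=1) + pseudo_mean
    m2 = den.mean(axis=1) + pseudo_mean
    log2fc = np.log2(m1 / m2)
    var_term = (m1 + alpha * m1**2) / (n1 * m1**2) + (m2 + alpha * m2**2) / (n2 * m2**2)
    se = np.sqrt(var_term) / np.log(2)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = np.concatenate([num, den], axis=1).mean(axis=1)

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": se,
            "stat": z,
            "pvalue": p,
            "padj": bh_adjust(p),
        },
        index=counts.counts.index[tested],
    )
    out.index.name = "gene"
    return out


def call_regulated(result: pd.DataFrame, thresholds: CallThresholds) -> pd.DataFrame:
    """Attach boolean up/down regulation calls (strict inequalities)."""
    if thresholds.use_adjusted:
        sig = result["padj"] < thresholds.padj_max
    else:
        sig = result["pvalue"] < thresholds.p_max
    out = result.copy()
    out["up"] = sig & (result["log2FC"] > thresholds.lfc_min)
    out["down"] = sig & (result["log2FC"] < -thresholds.lfc_min)
    return out


def run_contrasts(
    counts: CountMatrix,
    specs: Sequence[ContrastSpec] | None = None,
    thresholds: CallThresholds | None = None,
    dispersions: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Convenience driver: size factors, dispersions, Wald + calls per contrast."""
    if specs is None:
        specs = [ContrastSpec.canonical(name) for name in CANONICAL_CONTRASTS]
    thresholds = thresholds or CallThresholds()
    factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, factors)
    return {
        spec.name: call_regulated(
            wald_contrast(counts, spec, factors, dispersions), thresholds
        )
        for spec in specs
    }


def build_call_table(
    results: Mapping[str, pd.DataFrame],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boolean up-call table (genes x contrasts) over a common gene universe.

    Genes untested in a contrast (all-zero in both groups) count as not up,
    matching the set-complement reading of "not upregulated".
    """
    if genes is None:
        universe: set[str] = set()
        for res in results.values():
            universe |= set(res.index)
        genes = sorted(universe)
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for name, res in results.items():
        table[name] = res["up"].reindex(genes, fill_value=False).astype(bool)
    return table
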