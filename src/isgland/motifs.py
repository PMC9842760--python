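"""DNA motif models, log-odds scanning, and hypergeometric enrichment.

Motifs are modelled either as position frequency matrices (PFM, JASPAR-style
text) scored by log-odds against a background base composition, or — for the
4-mer interferon-response core element (IRE, ``TTTC``) — as an exact string
matcher, since a 4-mer PWM at any usable threshold degenerates to string
matching anyway.

Scanning covers both strands; reverse-strand hit coordinates are reported in
the forward-strand frame.  Enrichment of a foreground region set against a
background uses the two-tailed (minimum-likelihood) hypergeometric test with
Benjamini-Hochberg adjustment across the motif set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .diffexpr import bh_adjust

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD_FRACTION = 0.8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes (N -> 4). Rejects other codes."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    if (codes == 255).any():
        bad = sorted({chr(b) for b in arr[codes == 255]})
        raise ValueError(f"sequence contains unsupported characters: {bad}")
    return codes


@dataclass(frozen=True)
class MotifHit:
    """A single motif match on a sequence, in forward-strand coordinates."""

    seq_id: str
    motif: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    score: float  # log-odds, bits


@dataclass
class PWM:
    """Position probability matrix with log-odds scoring.

    ``probs`` has shape (4, L), rows in A/C/G/T order, columns summing to 1
    (after pseudocount regularisation).  Score of a window is
    sum_j log2(p[base_j, j] / background[base_j]); N contributes 0 bits.
    """

    name: str
    probs: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("PFM must be 4 x L with L >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PFM columns must sum to 1")
        # zero cells are tolerated (zero-pseudocount matrices score -inf on
        # mismatches, which can never pass a positive threshold)
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold fraction must be in (0, 1]")

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: np.ndarray | None = None,
        threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        reg = counts + pseudocount
        probs = reg / reg.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(name, probs, pseudocount, bg, threshold_fraction)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(5, L) score matrix in bits; the fifth row (N) is all zeros."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[:, None])
        return np.vstack([lo, np.zeros((1, self.length))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:4].max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))

    def score_window(self, window: str) -> float:
        """Score a single L-mer (brute-force entry point; scanning is vectorised)."""
        codes = _encode(window)
        if codes.size != self.length:
            raise ValueError(f"window length {codes.size} != motif length {self.length}")
        lo = self.log_odds
        return float(sum(lo[c, j] for j, c in enumerate(codes)))

    def _scan_strand(self, codes: np.ndarray) -> np.ndarray:
        L = self.length
        n_win = codes.size - L + 1
        lo = self.log_odds
        scores = np.zeros(n_win)
        for j in range(L):
            scores += lo[codes[j : j + n_win], j]
        return scores

    def scan(self, seq_id: str, seq: str) -> list[MotifHit]:
        codes = _encode(seq)
        if codes.size < self.length:
            raise ValueError("sequence shorter than motif")
        cutoff = self.threshold_fraction * self.max_score
        hits: list[MotifHit] = []
        fwd = self._scan_strand(codes)
        for i in np.nonzero(fwd >= cutoff)[0]:
            hits.append(MotifHit(seq_id, self.name, int(i), "+", float(fwd[i])))
        rc = _encode(reverse_complement(seq))
        rev = self._scan_strand(rc)
        n = codes.size
        for i in np.nonzero(rev >= cutoff)[0]:
            start = n - self.length - int(i)
            hits.append(MotifHit(seq_id, self.name, start, "-", float(rev[i])))
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits


@dataclass
class ExactMotif:
    """Exact-string motif matcher (both strands); used for the TTTC core element."""

    name: str
    site: str

    def __post_init__(self) -> None:
        self.site = self.site.upper()
        if not set(self.site) <= set(_BASES):
            raise ValueError("exact motif site must be ACGT only")

    @property
    def length(self) -> int:
        return len(self.site)

    @property
    def consensus(self) -> str:
        return self.site

    @property
    def max_score(self) -> float:
        # uniform background, exact match: 2 bits per position
        return 2.0 * len(self.site)

    def scan(self, seq_id: str, seq: str) -> list[MotifHit]:
        s = seq.upper()
        _encode(s)  # validate alphabet
        if len(s) < self.length:
            raise ValueError("sequence shorter than motif")
        hits: list[MotifHit] = []
        targets = ((self.site, "+"), (reverse_complement(self.site), "-"))
        for target, strand in targets:
            start = s.find(target)
            while start != -1:
                hits.append(MotifHit(seq_id, self.name, start, strand, self.max_score))
                start = s.find(target, start + 1)
        # a palindromic site would be double-reported; keep one record per placement
        if self.site == reverse_complement(self.site):
            hits = [h for h in hits if h.strand == "+"]
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits


Motif = PWM | ExactMotif


def read_pfm(path: str | Path, **kwargs) -> list[PWM]:
    """Read JASPAR-style PFM text (``>name`` header, four A/C/G/T rows)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([list(rec.counts[b]) for b in _BASES], dtype=float)
        out.append(PWM.from_counts(rec.name, counts, **kwargs))
    return out


def write_pfm(motif: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif.name}\n")
        # write probabilities scaled to 100 "counts" for readability
        scaled = motif.probs * 100
        for base, row in zip(_BASES, scaled):
            cells = " ".join(f"{v:6.2f}" for v in row)
            fh.write(f"{base} [ {cells} ]\n")


def load_default_motifs(
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> dict[str, Motif]:
    """Bundled motif set: ISRE, GAS, NF-kB PFMs plus the exact TTTC IRE."""
    out: dict[str, Motif] = {}
    data_dir = resources.files("isgland") / "data" / "motifs"
    for name in ("ISRE", "GAS", "NFKB"):
        with resources.as_file(data_dir / f"{name}.jaspar") as p:
            (pwm,) = read_pfm(p, threshold_fraction=threshold_fraction)
        out[pwm.name] = pwm
    out["IRE"] = ExactMotif("IRE", "TTTC")
    return out


def scan_sequence(motif: Motif, seq: str, seq_id: str = "seq") -> list[MotifHit]:
    return motif.scan(seq_id, seq)


def scan_sequences(
    motifs: Mapping[str, Motif] | Iterable[Motif],
    seqs: Mapping[str, str],
) -> pd.DataFrame:
    """Scan every sequence with every motif; returns a tidy hit table."""
    if isinstance(motifs, Mapping):
        motif_list = list(motifs.values())
    else:
        motif_list = list(motifs)
    rows = []
    for seq_id, seq in seqs.items():
        for motif in motif_list:
            if len(seq) < motif.length:
                continue
            rows.extend(motif.scan(seq_id, seq))
    return hits_to_frame(rows)


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.seq_id, h.motif, h.start, h.strand, h.score) for h in hits],
        columns=["seq_id", "motif", "start", "strand", "score"],
    )


def motif_presence(
    hits: pd.DataFrame,
    gene_regions: Mapping[str, Sequence[str]],
    motif_names: Sequence[str],
) -> pd.Series:
    """Per-gene boolean: does any of the gene's regions carry any listed motif?

    A gene mapped to no region is reported False with a warning, mirroring the
    "no evidence" reading of absent data.
    """
    hit_regions = {
        m: set(hits.loc[hits["motif"] == m, "seq_id"]) for m in motif_names
    }
    out = {}
    for gene, regions in gene_regions.items():
        if len(regions) == 0:
            warnings.warn(f"gene {gene} has no mapped regions; presence set to False")
            out[gene] = False
            continue
        out[gene] = any(
            r in hit_regions[m] for m in motif_names for r in regions
        )
    return pd.Series(out, name="motif_presence", dtype=bool)


def two_tailed_hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Two-tailed hypergeometric p under the minimum-likelihood rule.

    Sums P(X = x) over the support for every x whose point probability does
    not exceed P(X = k).  Point probabilities are compared in exact integer
    arithmetic (the hypergeometric pmf numerators C(K,x)·C(N-K,n-x) are
    integers), so ties are resolved exactly.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError("require 0 <= k <= n <= N and k <= K <= N")
    lo = max(0, n - (N - K))
    hi = min(n, K)
    weights = {x: math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)}
    w_k = weights[k]
    num = sum(w for w in weights.values() if w <= w_k)
    return float(Fraction(num, math.comb(N, n)))


def upper_tail_hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """One-sided enrichment p: P(X >= k)."""
    lo = max(0, n - (N - K))
    hi = min(n, K)
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(max(k, lo), hi + 1))
    return float(Fraction(num, math.comb(N, n)))


def hypergeometric_enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    hits: pd.DataFrame,
    motif_names: Sequence[str] | None = None,
    alternative: str = "two-tailed",
) -> pd.DataFrame:
    """Per-motif enrichment of foreground regions against a background superset.

    A region counts as "hit" if it carries >= 1 match of the motif.  Returns a
    table with k, n, K, N, fold enrichment (k/n)/(K/N) and BH-adjusted p
    across the motif set.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    if not bg:
        raise ValueError("background is empty")
    if motif_names is None:
        motif_names = sorted(hits["motif"].unique())
    N, n = len(bg), len(fg)
    rows = []
    for motif in motif_names:
        hit_ids = set(hits.loc[hits["motif"] == motif, "seq_id"])
        K = len(bg & hit_ids)
        k = len(fg & hit_ids)
        if alternative == "two-tailed":
            p = two_tailed_hypergeom_p(k, n, K, N)
        elif alternative == "greater":
            p = upper_tail_hypergeom_p(k, n, K, N)
        else:
            raise ValueError(f"unknown alternative: {alternative}")
        fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
        rows.append((motif, k, n, K, N, fold, p))
    out = pd.DataFrame(
        rows, columns=["motif", "k", "n", "K", "N", "fold_enrichment", "pvalue"]
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
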