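"""Four-contrast ISG taxonomy: typical vs. atypical ISGs, heatmap clusters,
and subdivision of atypical ISGs into reported / hidden / non-canonical.

The logic operates on boolean up-regulation calls for the four canonical
contrasts of the genotype x interferon design (see :mod:`isgland.diffexpr`):

* typical ISG      — induced by IFN in both genotypes: up(C1) and up(C2)
* atypical ISG     — induced by IFN only in the KO: up(C2) and not up(C1)
* cluster A        — up(C1) and up(C2), not already shifted at baseline (not up(C4))
* cluster D        — up(C3) and up(C2), not up(C1) and not up(C4)

Atypical ISGs found in a known-ISG reference list are "reported"; the rest
split into "hidden" (ISRE/STAT1 motif or binding evidence in their regulatory
regions) and "noncanonical" (no such evidence).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

PRIMARY_LABELS = ("typical", "atypical", "none")
SUBLABELS = ("reported", "hidden", "noncanonical", "unassigned")

_REQUIRED_MINIMAL = ("C1", "C2")
_REQUIRED_CLUSTERS = ("C1", "C2", "C3", "C4")


def _check_contrasts(calls: pd.DataFrame, required: Iterable[str]) -> None:
    missing = [c for c in required if c not in calls.columns]
    if missing:
        raise ValueError(f"call table lacks contrast(s): {missing}")


def classify_typical_atypical(calls: pd.DataFrame) -> pd.DataFrame:
    """Assign the typical / atypical / none primary label from C1 and C2 calls."""
    _check_contrasts(calls, _REQUIRED_MINIMAL)
    c1 = calls["C1"].astype(bool)
    c2 = calls["C2"].astype(bool)
    label = pd.Series("none", index=calls.index, name="label")
    label[c2 & c1] = "typical"
    label[c2 & ~c1] = "atypical"
    out = pd.DataFrame({"label": label})
    out["sublabel"] = pd.Series(pd.NA, index=calls.index, dtype="object")
    return out


def assign_heatmap_clusters(calls: pd.DataFrame) -> pd.DataFrame:
    """Boolean flags for heatmap clusters A and D.

    A: IFN-induced in both genotypes with no baseline KO shift.
    D: KO-specific IFN induction (up in C2 and C3, not C1) with no baseline
    shift.  Clusters B and C are never defined and are not assigned.
    """
    _check_contrasts(calls, _REQUIRED_CLUSTERS)
    c1, c2, c3, c4 = (calls[c].astype(bool) for c in _REQUIRED_CLUSTERS)
    return pd.DataFrame(
        {
            "cluster_A": c1 & c2 & ~c4,
            "cluster_D": c3 & c2 & ~c1 & ~c4,
        },
        index=calls.index,
    )


def subdivide_atypical(
    classification: pd.DataFrame,
    known_isgs: Iterable[str],
    motif_presence: pd.Series | Mapping[str, bool],
) -> pd.DataFrame:
    """Split atypical ISGs into reported / hidden / noncanonical.

    ``known_isgs`` plays the role of the reference-database lookup; atypical
    genes in the list are "reported".  The remainder are "hidden" when
    ``motif_presence`` (ISRE/GAS motif hit or user-supplied binding evidence)
    is True, else "noncanonical".  An atypical gene missing from
    ``motif_presence`` is left "unassigned" with a warning.
    """
    known = set(known_isgs)
    presence = pd.Series(motif_presence, dtype="boolean")
    out = classification.copy()
    atypical = out.index[out["label"] == "atypical"]
    sub = pd.Series(pd.NA, index=out.index, dtype="object")
    missing = []
    for gene in atypical:
        if gene in known:
            sub[gene] = "reported"
        elif gene not in presence.index or pd.isna(presence[gene]):
            sub[gene] = "unassigned"
            missing.append(gene)
        elif bool(presence[gene]):
            sub[gene] = "hidden"
        else:
            sub[gene] = "noncanonical"
    if missing:
        warnings.warn(
            f"{len(missing)} atypical gene(s) lack motif/binding evidence data; "
            "left unassigned"
        )
    out["sublabel"] = sub
    return out


def classify(
    calls: pd.DataFrame,
    known_isgs: Iterable[str] | None = None,
    motif_presence: pd.Series | Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Full classification: primary label, sublabel, cluster flags."""
    out = classify_typical_atypical(calls)
    if set(_REQUIRED_CLUSTERS) <= set(calls.columns):
        out = out.join(assign_heatmap_clusters(calls))
    if known_isgs is not None and motif_presence is not None:
        out = subdivide_atypical(out, known_isgs, motif_presence)
    return out


def classification_report(classification: pd.DataFrame) -> dict:
    """Summary counts per class / sublabel / cluster plus the crosstab."""
    n = len(classification)
    label_counts = {
        lab: int((classification["label"] == lab).sum()) for lab in PRIMARY_LABELS
    }
    sub_counts = {
        lab: int((classification.get("sublabel") == lab).sum()) for lab in SUBLABELS
    }
    clusters = {}
    crosstab: dict[str, dict[str, int]] = {}
    for col in ("cluster_A", "cluster_D"):
        if col in classification.columns:
            clusters[col] = int(classification[col].sum())
            crosstab[col] = {
                lab: int(
                    (classification[col] & (classification["label"] == lab)).sum()
                )
                for lab in PRIMARY_LABELS
            }
    return {
        "n_genes": n,
        "labels": label_counts,
        "atypical_sublabels": sub_counts,
        "clusters": clusters,
        "cluster_by_label": crosstab,
    }


def write_report(
    classification: pd.DataFrame, tsv_path: str | Path, json_path: str | Path
) -> dict:
    """Write the per-gene table (TSV) and the summary (JSON); returns the summary."""
    classification.to_csv(tsv_path, sep="\t", index_label="gene")
    summary = classification_report(classification)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
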