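"""Overlap accounting, over-representation tests and recovery metrics.

The end of the workflow asks: how many of the differentially expressed
genes from each contrast were already claimed by a confounder gene set
(composition, time-of-day, handling stress, individual effect)?  Overlap
percentages mirror the published table layout (empty DEG rows rendered as
"-"); enrichment uses the upper-tail hypergeometric test against the array
background.  ``recovery_metrics`` scores called sets against the synthetic
generator's ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import GeneSet, Provenance, ValidationError
from .synthetic import GeneClass, GroundTruth

__all__ = [
    "OverlapTable",
    "overlap_table",
    "hypergeometric_ora",
    "ora_table",
    "deg_count_table",
    "recovery_metrics",
]


@dataclass
class OverlapTable:
    """Percent of each contrast's DEGs found in each confounder set."""

    contrasts: list[str]
    set_names: list[str]               # confounder sets plus "All"
    deg_counts: dict[str, int]
    fractions: pd.DataFrame            # exact fractions in [0, 1], NaN for empty DEG rows

    def render(self) -> pd.DataFrame:
        """Display table: integer percents rounded half-up, '-' for empty rows."""
        def cell(contrast, name):
            v = self.fractions.loc[contrast, name]
            if np.isnan(v):
                return "-"
            return str(int(math.floor(v * 100 + 0.5)))
        out = pd.DataFrame(
            [[self.deg_counts[c]] + [cell(c, s) for s in self.set_names]
             for c in self.contrasts],
            index=self.contrasts,
            columns=["DEGs"] + self.set_names,
        )
        return out


def overlap_table(deg_sets: Mapping[str, GeneSet],
                  confounder_sets: Sequence[GeneSet]) -> OverlapTable:
    """Per-contrast percent of DEGs present in each confounder set.

    The "All" column uses the union of the confounder sets, so it is at
    least the maximum and at most the sum of the single-set columns.
    """
    names = [s.name for s in confounder_sets]
    union = frozenset().union(*(s.members for s in confounder_sets)) \
        if confounder_sets else frozenset()
    cols = names + ["All"]
    rows = {}
    counts = {}
    for contrast, deg in deg_sets.items():
        counts[contrast] = len(deg)
        if len(deg) == 0:
            rows[contrast] = [np.nan] * len(cols)
            continue
        vals = [len(deg.members & s.members) / len(deg) for s in confounder_sets]
        vals.append(len(deg.members & union) / len(deg))
        rows[contrast] = vals
    fractions = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return OverlapTable(
        contrasts=list(deg_sets),
        set_names=cols,
        deg_counts=counts,
        fractions=fractions,
    )


def hypergeometric_ora(deg: GeneSet, gene_set: GeneSet,
                       background_size: int) -> float:
    """Upper-tail hypergeometric over-representation probability.

    P(X >= k) for X ~ Hypergeometric(N=background, K=|set|, n=|DEG|) with
    k the observed overlap.
    """
    n, K = len(deg), len(gene_set)
    if n > background_size or K > background_size:
        raise ValidationError("set larger than the background")
    k = len(deg.members & gene_set.members)
    if k > min(n, K):
        raise AssertionError("overlap exceeds min(|deg|, |set|): set-algebra bug")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, background_size, K, n))


def ora_table(deg_sets: Mapping[str, GeneSet],
              confounder_sets: Sequence[GeneSet],
              background_size: int) -> pd.DataFrame:
    """Upper-tail ORA probability per (contrast, confounder set)."""
    rows = {}
    for contrast, deg in deg_sets.items():
        if len(deg) == 0:
            rows[contrast] = [np.nan] * len(confounder_sets)
        else:
            rows[contrast] = [hypergeometric_ora(deg, s, background_size)
                              for s in confounder_sets]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.name for s in confounder_sets])


def deg_count_table(scan_with: Mapping[tuple[str, str], GeneSet],
                    scan_without: Mapping[tuple[str, str], GeneSet]
                    ) -> pd.DataFrame:
    """DEG counts per contrast, without vs with the individual random term."""
    if set(scan_with) != set(scan_without):
        raise ValidationError("the two scans cover different contrasts")
    rows = []
    for contrast in scan_with:
        rows.append({
            "contrast": f"{contrast[0]} vs {contrast[1]}",
            "without_individual": len(scan_without[contrast]),
            "with_individual": len(scan_with[contrast]),
        })
    return pd.DataFrame(rows)


def recovery_metrics(called: Mapping[str, GeneSet], truth: GroundTruth
                     ) -> pd.DataFrame:
    """Precision/recall/F1 of called sets against planted gene classes.

    ``called`` maps a planted class name (e.g. "composition") to the gene
    set the pipeline produced for it.  Classes without a called set get
    recall 0 and missing precision.
    """
    class_names = {c.value for c in GeneClass}
    for name in called:
        if name not in class_names:
            raise ValidationError(f"unknown planted class {name!r}")
    rows = []
    for cls in GeneClass:
        if cls is GeneClass.NULL:
            continue
        planted = set(truth.genes_of_class(cls))
        if not planted:
            continue
        got = called.get(cls.value)
        if got is None or len(got) == 0:
            rows.append({"class": cls.value, "n_planted": len(planted),
                         "n_called": 0, "precision": np.nan, "recall": 0.0,
                         "f1": np.nan})
            continue
        tp = len(got.members & planted)
        precision = tp / len(got)
        recall = tp / len(planted)
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        rows.append({"class": cls.value, "n_planted": len(planted),
                     "n_called": len(got), "precision": precision,
                     "recall": recall, "f1": f1})
    return pd.DataFrame(rows)
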