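"""The four confounder selection rules.

* time-of-day: per-mouse fold-change screen (|log2 FC| >= threshold between
  some pair of time points in *every* mouse of the group) followed by a
  low-variance tail cut among the candidates;
* handling/biopsy stress: relabel recovery times to biopsy order (the late
  series restarts at 7.5 h), test biopsy-order contrasts, and keep the
  low-SD differentially expressed genes;
* individual effect: genes whose largest per-individual model coefficient
  exceeds a cut, minus anything already claimed by another confounder set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .cluster import VarianceRanking
from .core_io import (
    EARLY_BIOPSY_MAP,
    LATE_BIOPSY_MAP,
    ExpressionMatrix,
    GeneSet,
    Provenance,
    SampleTable,
    Series,
    ValidationError,
)

__all__ = [
    "FcScreenResult",
    "relabel_biopsy_order",
    "fc_screen",
    "low_variance_tail",
    "handling_stress_set",
    "individual_effect_set",
]


def relabel_biopsy_order(samples: SampleTable,
                         late_b1_includes_t0: bool = True) -> SampleTable:
    """Assign biopsy order from recovery time.

    Early series: t0..t5 -> b1..b6.  Late series restarts at 7.5 h: t0 and
    t7.5 both map to b1, then t9->b2, t10.5->b3, t12->b4.  With
    ``late_b1_includes_t0=False`` the late t0 samples are dropped instead
    (the alternative reading of the restart).
    """
    records = []
    for r in samples:
        bmap = EARLY_BIOPSY_MAP if r.series is Series.EARLY else LATE_BIOPSY_MAP
        if r.recovery_time_h not in bmap:
            raise ValidationError(
                f"sample {r.sample_id!r}: recovery time {r.recovery_time_h} h "
                f"not on the {r.series.value} grid")
        if (not late_b1_includes_t0 and r.series is Series.LATE
                and r.recovery_time_h == 0.0):
            continue
        records.append(replace(r, biopsy_order=bmap[r.recovery_time_h]))
    return SampleTable(records)


@dataclass
class FcScreenResult:
    """Per-gene, per-individual log2 range and the every-mouse pass flag."""

    gene_ids: list[str]
    individual_ids: list[str]
    ranges: np.ndarray       # (G, I) max - min log2 over each mouse's samples
    threshold_log2: float
    passed: np.ndarray       # (G,) bool

    @property
    def passing_genes(self) -> tuple[str, ...]:
        return tuple(g for g, p in zip(self.gene_ids, self.passed) if p)


def fc_screen(matrix: ExpressionMatrix, samples: SampleTable,
              threshold_log2: float) -> FcScreenResult:
    """Keep genes with log2 range >= threshold within *every* individual.

    The range is max - min over a mouse's time points, i.e. the largest
    fold change between any two of its samples.
    """
    by_ind = samples.by_individual()
    if not by_ind:
        raise ValidationError("no samples in group")
    inds = sorted(by_ind)
    ranges = np.empty((matrix.n_genes, len(inds)))
    for j, ind in enumerate(inds):
        recs = by_ind[ind]
        if len(recs) < 2:
            raise ValidationError(
                f"individual {ind!r} has {len(recs)} sample(s); need >=2")
        x = matrix.sample_cols([r.sample_id for r in recs])
        ranges[:, j] = x.max(axis=1) - x.min(axis=1)
    passed = np.all(ranges >= threshold_log2, axis=1)
    return FcScreenResult(
        gene_ids=list(matrix.gene_ids),
        individual_ids=inds,
        ranges=ranges,
        threshold_log2=threshold_log2,
        passed=passed,
    )


def low_variance_tail(candidates: Sequence[str], ranking: VarianceRanking,
                      k: int, name: str = "TD-tail") -> GeneSet:
    """The k candidates with the lowest SD in the ranking (ties by gene ID)."""
    candidates = list(dict.fromkeys(candidates))
    missing = [g for g in candidates if g not in ranking.sd]
    if missing:
        raise ValidationError(f"candidates not in ranking: {missing[:5]}")
    if not 0 <= k <= len(candidates):
        raise ValidationError(
            f"tail size k={k} exceeds {len(candidates)} candidates")
    chosen = sorted(candidates, key=lambda g: (ranking.sd[g], g))[:k]
    return GeneSet(
        name=name,
        provenance=Provenance.TD,
        genes=tuple(chosen),
        description=f"low-variance tail (k={k}) of fold-change candidates",
        empty_allowed=True,
    )


def handling_stress_set(deg_genes: Sequence[str], ranking: VarianceRanking,
                        sd_threshold: float, name: str = "HS-A") -> GeneSet:
    """Subset of biopsy-order DEGs with SD strictly below the threshold."""
    deg_genes = list(dict.fromkeys(deg_genes))
    missing = [g for g in deg_genes if g not in ranking.sd]
    if missing:
        raise ValidationError(f"DEGs not in ranking: {missing[:5]}")
    kept = [g for g in deg_genes if ranking.sd[g] < sd_threshold]
    return GeneSet(
        name=name,
        provenance=Provenance.HS,
        genes=tuple(kept),
        description=f"biopsy-order DEGs with SD < {sd_threshold}",
        empty_allowed=True,
    )


def individual_effect_set(coefs: Mapping[str, np.ndarray],
                          coef_threshold: float,
                          exclude: Sequence[GeneSet] = (),
                          inclusive: bool = False,
                          name: str = "IM-A") -> GeneSet:
    """Genes whose largest |per-individual coefficient| exceeds the cut.

    ``coefs`` maps gene -> vector of predicted individual effects (one per
    mouse).  The comparison is strict by default ("higher than 0.5");
    ``inclusive=True`` switches to >=.  Genes present in any exclusion set
    are removed afterwards.
    """
    if not coefs:
        raise ValidationError("empty coefficient collection")
    excluded = set().union(*(s.members for s in exclude)) if exclude else set()
    chosen = []
    for gene, c in coefs.items():
        m = float(np.max(np.abs(np.asarray(c, dtype=float))))
        hit = m >= coef_threshold if inclusive else m > coef_threshold
        if hit and gene not in excluded:
            chosen.append(gene)
    return GeneSet(
        name=name,
        provenance=Provenance.IM,
        genes=tuple(chosen),
        description=(f"max |individual coefficient| "
                     f"{'>=' if inclusive else '>'} {coef_threshold}, "
                     "other confounder sets excluded"),
        empty_allowed=True,
    )
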