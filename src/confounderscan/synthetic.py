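"""Synthetic repeated-biopsy expression data with planted confounders.

The generator emulates the wild-type arm of the motivating experiment: 16
mice split over four groups (early series treated/untreated at the high UV
dose, late series treated/untreated at the low dose), with 6 consecutive
biopsies at 0,1,2,3,4,5 h for early mice and 5 biopsies at 0,7.5,9,10.5,12 h
for late mice — 88 samples in total.

Five gene classes are planted on top of i.i.d. Gaussian log2 noise:

* ``composition`` — cell-type marker genes whose measured level is the log2
  of a mixture of per-cell-type intensities weighted by per-sample cell
  fractions; fractions are Dirichlet draws around a per-individual mean
  composition, so profiles are near-identical within a mouse and unrelated
  between mice.
* ``circadian`` — sinusoidal time-of-day oscillation with a per-individual
  phase; recovery time is deliberately confounded with clock time (all
  series start at the same clock hour).
* ``handling`` — a linear trend in biopsy order (cumulative handling /
  biopsy stress), independent of recovery time conditional on order.
* ``individual`` — a per-mouse random intercept, constant over that mouse's
  samples.
* ``treatment`` — an additive shift in treated samples (optionally only at
  selected recovery times), the "real" signal the confounders mimic.

Every gene draws its noise from a seed-sequence substream keyed by the gene
index, so changing class counts never reshuffles other genes' noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    EARLY_BIOPSY_MAP,
    LATE_BIOPSY_MAP,
    ConfigError,
    Dose,
    ExpressionMatrix,
    GeneSet,
    Provenance,
    SampleRecord,
    SampleTable,
    Series,
)

__all__ = [
    "GeneClass",
    "SimulationConfig",
    "GroundTruth",
    "build_design",
    "simulate_experiment",
    "write_ground_truth",
]


class GeneClass(str, Enum):
    COMPOSITION = "composition"
    CIRCADIAN = "circadian"
    HANDLING = "handling"
    INDIVIDUAL = "individual"
    TREATMENT = "treatment"
    NULL = "null"


@dataclass
class SimulationConfig:
    """Parameters of the planted-confounder generator.

    Effect-size defaults are calibrated so the planted classes are clearly
    expressed yet near the workflow's published selection thresholds:
    circadian amplitude 1.5 log2 units against the |log2 FC| >= 1 screen,
    handling slope 0.4 log2/biopsy step, individual-effect SD 0.8 against
    the |coefficient| > 0.5 rule, composition marker spread 2 log2 units
    (marker genes 4 log2 units apart between their own and other cell
    types, echoing the >30-fold cell-type differences seen in real skin
    biopsies), and measurement noise SD 0.2.
    """

    n_genes: int = 2000
    n_individuals: int = 16
    n_composition: int = 0
    n_circadian: int = 0
    n_handling: int = 0
    n_individual: int = 0
    n_treatment: int = 0
    sigma_e: float = 0.2
    sigma_m: float = 0.8
    circadian_amplitude: float = 1.5
    circadian_period_h: float = 24.0
    circadian_phase_sd_h: float = 0.5
    clock_start_h: float = 0.0
    handling_slope: float = 0.4
    n_cell_types: int = 2
    composition_spread: float = 2.0
    dirichlet_concentration: float = 3.0
    individual_mean_concentration: float = 6.0
    treatment_effect: float = 1.0
    treatment_times: Optional[tuple[float, ...]] = None  # None -> all t > 0
    #: individual-intercept SD of treatment genes (None -> sigma_m): genes
    #: that truly respond to treatment still differ between mice, which is
    #: exactly what makes the individual term matter in DEG scans
    sigma_m_treatment: Optional[float] = None
    #: optional individual-intercept overlays for the circadian and handling
    #: classes (0 = pure mechanism); real time-of-day gene groups carry
    #: sizable between-mouse offsets on top of their oscillation
    sigma_m_circadian: float = 0.0
    sigma_m_handling: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = self.class_counts()
        if sum(counts.values()) > self.n_genes:
            raise ConfigError(
                f"class counts sum to {sum(counts.values())} > n_genes={self.n_genes}")
        if self.sigma_e < 0 or self.sigma_m < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if self.dirichlet_concentration <= 0 or self.individual_mean_concentration <= 0:
            raise ConfigError("Dirichlet concentrations must be positive")
        if self.n_cell_types < 2:
            raise ConfigError("need at least 2 cell types")

    def class_counts(self) -> dict[GeneClass, int]:
        return {
            GeneClass.COMPOSITION: self.n_composition,
            GeneClass.CIRCADIAN: self.n_circadian,
            GeneClass.HANDLING: self.n_handling,
            GeneClass.INDIVIDUAL: self.n_individual,
            GeneClass.TREATMENT: self.n_treatment,
        }


@dataclass
class GroundTruth:
    """Mapping from gene to planted class plus the planted parameters."""

    gene_class: dict[str, GeneClass]
    params: dict[str, dict]
    individual_phase_h: dict[str, float]
    individual_composition: dict[str, np.ndarray]

    def genes_of_class(self, cls: GeneClass) -> tuple[str, ...]:
        return tuple(g for g, c in self.gene_class.items() if c is cls)

    def to_gene_sets(self) -> list[GeneSet]:
        out = []
        for cls in GeneClass:
            genes = self.genes_of_class(cls)
            if genes:
                out.append(GeneSet(
                    name=f"truth-{cls.value}",
                    provenance=Provenance.TRUTH,
                    genes=genes,
                    description=f"planted {cls.value} genes",
                ))
        return out


def build_design(config: SimulationConfig) -> SampleTable:
    """Lay out the four-group repeated-biopsy design.

    Individuals are split evenly over (early, high dose, treated),
    (early, untreated), (late, low dose, treated), (late, untreated).
    """
    n = config.n_individuals
    if n % 4 != 0 or n <= 0:
        raise ConfigError(
            f"n_individuals={n} not divisible into the four design groups")
    per_group = n // 4
    groups = [
        (Series.EARLY, Dose.HIGH, True),
        (Series.EARLY, Dose.NONE, False),
        (Series.LATE, Dose.LOW, True),
        (Series.LATE, Dose.NONE, False),
    ]
    records = []
    ind = 0
    for series, dose, treated in groups:
        for _ in range(per_group):
            ind += 1
            ind_id = f"M{ind:02d}"
            for t in series.times:
                records.append(SampleRecord(
                    sample_id=f"{ind_id}_t{_fmt_time(t)}",
                    individual_id=ind_id,
                    series=series,
                    recovery_time_h=t,
                    dose=dose,
                    treated=treated,
                ))
    return SampleTable(records)


def _fmt_time(t: float) -> str:
    return f"{t:g}".replace(".", "p")


def _biopsy_step(rec: SampleRecord) -> int:
    """0-based biopsy index (b - 1) used by the handling-stress plant.

    Uses the same order convention as the relabeling stage: the late series
    restarts at 7.5 h, so t0 and t7.5 are both step 0.
    """
    bmap = EARLY_BIOPSY_MAP if rec.series is Series.EARLY else LATE_BIOPSY_MAP
    return bmap[rec.recovery_time_h] - 1


def simulate_experiment(
    config: SimulationConfig, design: SampleTable
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a log2 expression matrix plus the planted ground truth.

    Same ``rng_seed`` gives bit-identical output for the same design.
    """
    n_samples = len(design)
    if n_samples == 0:
        raise ConfigError("empty design")
    individuals = design.individual_ids
    recs = design.records

    # shared (sample-level) structure: per-individual circadian phase,
    # per-individual mean cell composition, per-sample cell fractions
    phases: dict[str, float] = {}
    comp_means: dict[str, np.ndarray] = {}
    for k, ind in enumerate(individuals):
        rng = np.random.default_rng([config.rng_seed, 1, k])
        phases[ind] = float(rng.normal(0.0, config.circadian_phase_sd_h))
        comp_means[ind] = rng.dirichlet(
            np.full(config.n_cell_types, config.individual_mean_concentration))
    fractions = np.empty((n_samples, config.n_cell_types))
    for s, rec in enumerate(recs):
        rng = np.random.default_rng([config.rng_seed, 2, s])
        alpha = config.dirichlet_concentration * comp_means[rec.individual_id]
        fractions[s] = rng.dirichlet(np.maximum(alpha, 1e-6))

    times = np.array([r.recovery_time_h for r in recs])
    steps = np.array([_biopsy_step(r) for r in recs])
    treated = np.array([r.treated for r in recs])
    phase_vec = np.array([phases[r.individual_id] for r in recs])
    ind_index = {ind: k for k, ind in enumerate(individuals)}
    ind_of_sample = np.array([ind_index[r.individual_id] for r in recs])

    # class assignment: contiguous blocks in gene order
    classes: list[GeneClass] = []
    for cls, count in config.class_counts().items():
        classes.extend([cls] * count)
    classes.extend([GeneClass.NULL] * (config.n_genes - len(classes)))

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    values = np.empty((config.n_genes, n_samples))
    gene_class: dict[str, GeneClass] = {}
    params: dict[str, dict] = {}

    omega = 2.0 * np.pi / config.circadian_period_h
    if config.treatment_times is None:
        treat_mask_base = treated & (times > 0)
    else:
        tt = set(config.treatment_times)
        treat_mask_base = treated & np.isin(times, sorted(tt))

    comp_count = 0
    for i, (gid, cls) in enumerate(zip(gene_ids, classes)):
        rng = np.random.default_rng([config.rng_seed, 0, i])
        mu = config.baseline_mean + config.baseline_sd * rng.standard_normal()
        eps = config.sigma_e * rng.standard_normal(n_samples)
        gene_class[gid] = cls
        p: dict = {"mu": mu}
        if cls is GeneClass.COMPOSITION:
            cell = comp_count % config.n_cell_types
            comp_count += 1
            a = np.full(config.n_cell_types, mu - config.composition_spread)
            a[cell] = mu + config.composition_spread
            y = np.log2(fractions @ np.exp2(a)) + eps
            p.update(cell_type=cell, a=a.tolist())
        elif cls is GeneClass.CIRCADIAN:
            amp = config.circadian_amplitude
            y = mu + amp * np.sin(
                omega * (times + config.clock_start_h + phase_vec)) + eps
            p.update(amplitude=amp)
            if config.sigma_m_circadian > 0:
                m = config.sigma_m_circadian * rng.standard_normal(len(individuals))
                y = y + m[ind_of_sample]
                p.update(sigma_m=config.sigma_m_circadian, m=m.tolist())
        elif cls is GeneClass.HANDLING:
            slope = config.handling_slope
            y = mu + slope * steps + eps
            p.update(slope=slope)
            if config.sigma_m_handling > 0:
                m = config.sigma_m_handling * rng.standard_normal(len(individuals))
                y = y + m[ind_of_sample]
                p.update(sigma_m=config.sigma_m_handling, m=m.tolist())
        elif cls is GeneClass.INDIVIDUAL:
            m = config.sigma_m * rng.standard_normal(len(individuals))
            y = mu + m[ind_of_sample] + eps
            p.update(sigma_m=config.sigma_m, m=m.tolist())
        elif cls is GeneClass.TREATMENT:
            delta = config.treatment_effect
            sm = (config.sigma_m if config.sigma_m_treatment is None
                  else config.sigma_m_treatment)
            m = sm * rng.standard_normal(len(individuals))
            y = mu + m[ind_of_sample] + delta * treat_mask_base + eps
            p.update(delta=delta, sigma_m=sm, m=m.tolist())
        else:
            y = mu + eps
        values[i] = y
        params[gid] = p

    matrix = ExpressionMatrix(gene_ids, design.sample_ids, values)
    truth = GroundTruth(
        gene_class=gene_class,
        params=params,
        individual_phase_h=phases,
        individual_composition=comp_means,
    )
    return matrix, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """TSV of per-gene class and planted parameters (JSON-ish repr column)."""
    rows = [
        {"gene_id": g, "gene_class": truth.gene_class[g].value,
         "params": repr(truth.params[g])}
        for g in truth.gene_class
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
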