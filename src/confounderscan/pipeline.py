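"""End-to-end orchestration of the confounder scan.

Fixed stage order (later stages depend on earlier sets): variance screen ->
seeded Ward clusters with the coherence flag (sample composition) ->
fold-change screen with low-variance tail (time of day) -> biopsy-order
relabeling, mixed model and Fs test with SD filter (handling stress) ->
individual-effect coefficients excluding all previous sets (individual) ->
DEG contrast scans -> overlap and over-representation reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import Dendrogram, VarianceRanking, extract_seeded_cluster, \
    top_variable_genes, ward_cluster
from .core_io import (
    ExpressionMatrix,
    GeneSet,
    PipelineConfig,
    Provenance,
    SampleTable,
    Series,
    ValidationError,
)
from .mixedstats import (
    FsTestResult,
    MixedModelCollection,
    estimate_qvalues,
    fit_mixed_model_matrix,
    fs_permutation_test,
    run_contrast_scan,
    within_arm_contrasts,
    between_arm_contrasts,
)
from .report import OverlapTable, deg_count_table, ora_table, overlap_table, \
    recovery_metrics
from .screens import (
    fc_screen,
    handling_stress_set,
    individual_effect_set,
    low_variance_tail,
    relabel_biopsy_order,
)
from .som import CoherenceReport, profile_coherence

log = logging.getLogger("confounderscan.pipeline")

__all__ = ["ConfounderScan", "scan_confounders", "run_deg_scans", "build_report"]

#: Biopsy-order contrasts actually tested (b5/b6 samples inform the fit only).
BIOPSY_CONTRASTS = (("b1", "b2"), ("b1", "b3"), ("b1", "b4"))


@dataclass
class ConfounderScan:
    """All confounder gene sets plus the intermediate evidence."""

    ranking: VarianceRanking
    dendrogram: Dendrogram
    sc_sets: list[GeneSet]
    sc_reports: dict[str, CoherenceReport]
    td_set: GeneSet
    td_candidates_early: tuple[str, ...]
    td_candidates_late: tuple[str, ...]
    hs_set: GeneSet
    hs_deg_union: tuple[str, ...]
    hs_tables: dict[tuple[str, str], FsTestResult]
    im_set: GeneSet
    im_fits: MixedModelCollection

    @property
    def confounder_sets(self) -> list[GeneSet]:
        return [s for s in [*self.sc_sets, self.td_set, self.hs_set, self.im_set]
                if len(s) > 0]


def _tail_k(config: PipelineConfig, explicit: Optional[int],
            n_candidates: int) -> int:
    if explicit is not None:
        return min(explicit, n_candidates)
    return math.ceil(config.variance_tail_quantile * n_candidates)


def scan_confounders(matrix: ExpressionMatrix, samples: SampleTable,
                     config: PipelineConfig,
                     sc_seed_sets: Sequence[GeneSet] = (),
                     sc_max_cluster_size: int = 300) -> ConfounderScan:
    """Run the four confounder screens on the untreated samples.

    ``sc_seed_sets`` are marker-gene seed lists (one set per suspected cell
    type); each seeded cluster is kept as a sample-composition set only if
    its coherence report shows the composition signature.
    """
    untreated = samples.filter(treated=False)
    if len(untreated) == 0:
        raise ValidationError("no untreated samples in the design")

    # 1. variance screen over all untreated samples
    top_n = min(config.top_n_variance, matrix.n_genes)
    ranking = top_variable_genes(matrix, untreated.sample_ids, top_n)
    log.info("variance screen: kept top %d of %d genes", top_n, matrix.n_genes)

    # 2. sample composition: seeded Ward clusters + coherence flag
    dendro = ward_cluster(matrix, ranking.top_genes)
    sc_sets: list[GeneSet] = []
    sc_reports: dict[str, CoherenceReport] = {}
    top_members = set(ranking.top_genes)
    for seed_set in sc_seed_sets:
        seeds = [g for g in seed_set.genes if g in top_members]
        if not seeds:
            log.warning("seed set %s: no seed in the top-variance genes; skipped",
                        seed_set.name)
            continue
        cluster = extract_seeded_cluster(
            dendro, seeds, max_size=sc_max_cluster_size,
            name=f"SC-{seed_set.name}")
        # coherence judged over the full design: composition variation is
        # treatment-independent and more individuals stabilize the
        # between-mouse estimate
        rep = profile_coherence(
            matrix, cluster.genes, samples,
            within_threshold=config.coherence_within_threshold,
            between_threshold=config.coherence_between_threshold)
        sc_reports[cluster.name] = rep
        if rep.composition_signature:
            sc_sets.append(cluster)
        else:
            log.info("cluster %s rejected: within=%.2f between=%.2f",
                     cluster.name, rep.within, rep.between)

    # 3. time of day: per-series FC screen, low-variance tails, union
    def series_candidates(series: Series) -> tuple[str, ...]:
        grp = untreated.filter(series=series)
        if len(grp) == 0:
            return ()
        return fc_screen(matrix, grp, config.fc_threshold_log2).passing_genes

    cand_early = series_candidates(Series.EARLY)
    cand_late = series_candidates(Series.LATE)
    tails = []
    if cand_early:
        tails.append(low_variance_tail(
            cand_early, ranking, _tail_k(config, config.variance_tail_k_early,
                                         len(cand_early)), name="TD-early"))
    if cand_late:
        tails.append(low_variance_tail(
            cand_late, ranking, _tail_k(config, config.variance_tail_k_late,
                                        len(cand_late)), name="TD-late"))
    td_genes = tuple(dict.fromkeys(g for t in tails for g in t.genes))
    td_set = GeneSet(name="TD-B", provenance=Provenance.TD, genes=td_genes,
                     description="time-of-day candidates, low-variance tail union",
                     empty_allowed=True)

    # 4. handling stress: relabel, biopsy-contrast Fs tests, SD filter
    relabeled = relabel_biopsy_order(untreated,
                                     late_b1_includes_t0=config.late_b1_includes_t0)
    hs_tables: dict[tuple[str, str], FsTestResult] = {}
    hs_deg: list[str] = []
    for k, contrast in enumerate(BIOPSY_CONTRASTS):
        res = fs_permutation_test(
            matrix, relabeled, contrast, n_perm=config.n_permutations,
            seed=int(np.random.default_rng([config.rng_seed, 10 + k])
                     .integers(2 ** 31)),
            random_individual=True, factor="biopsy")
        res.qvalues = estimate_qvalues(res.pvalues).qvalues
        hs_tables[contrast] = res
        hs_deg.extend(g for g, q in zip(res.gene_ids, res.qvalues)
                      if q <= config.q_threshold)
    hs_deg_union = tuple(dict.fromkeys(hs_deg))
    hs_set = handling_stress_set(hs_deg_union, ranking,
                                 config.handling_sd_threshold)
    log.info("handling stress: %d biopsy DEGs, %d below SD %.2f",
             len(hs_deg_union), len(hs_set), config.handling_sd_threshold)

    # 5. individual effect: mixed-model coefficients, other sets excluded
    im_fits = fit_mixed_model_matrix(matrix, untreated, fixed="dose_time",
                                     random_individual=True)
    exclusions = [s for s in [*sc_sets, td_set, hs_set] if len(s) > 0]
    im_set = individual_effect_set(
        im_fits.individual_coef_map(), config.individual_coef_threshold,
        exclude=exclusions, inclusive=config.individual_coef_inclusive)

    return ConfounderScan(
        ranking=ranking, dendrogram=dendro,
        sc_sets=sc_sets, sc_reports=sc_reports,
        td_set=td_set, td_candidates_early=tuple(cand_early),
        td_candidates_late=tuple(cand_late),
        hs_set=hs_set, hs_deg_union=hs_deg_union, hs_tables=hs_tables,
        im_set=im_set, im_fits=im_fits,
    )


def run_deg_scans(matrix: ExpressionMatrix, samples: SampleTable,
                  config: PipelineConfig,
                  contrasts: Optional[Sequence[tuple[str, str]]] = None,
                  include_between_arm: bool = True):
    """Paired DEG scans with and without the individual random term."""
    if contrasts is None:
        contrasts = list(within_arm_contrasts(samples))
        if include_between_arm:
            contrasts += list(between_arm_contrasts(samples))
    with_sets, with_tables = run_contrast_scan(
        matrix, samples, contrasts, random_individual=True,
        q_threshold=config.q_threshold, n_perm=config.n_permutations,
        seed=config.rng_seed)
    without_sets, without_tables = run_contrast_scan(
        matrix, samples, contrasts, random_individual=False,
        q_threshold=config.q_threshold, n_perm=config.n_permutations,
        seed=config.rng_seed)
    return {
        "contrasts": list(contrasts),
        "with": {"sets": with_sets, "tables": with_tables},
        "without": {"sets": without_sets, "tables": without_tables},
    }


def build_report(deg_sets, confounder_sets: Sequence[GeneSet],
                 background_size: int, truth=None, truth_calls=None):
    """Assemble overlap, ORA and (optionally) recovery tables."""
    named = {f"{a} vs {b}": s for (a, b), s in deg_sets.items()}
    out = {
        "overlap": overlap_table(named, confounder_sets),
        "ora": ora_table(named, confounder_sets, background_size),
    }
    if truth is not None and truth_calls is not None:
        out["recovery"] = recovery_metrics(truth_calls, truth)
    return out
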