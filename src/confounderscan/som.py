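"""Per-individual 2x2 self-organizing maps and profile-coherence scoring.

The visual argument behind the sample-composition diagnosis is that a
composition-driven gene set shows near-identical scaled profiles *within*
each individual (all member genes track the same cell fraction) while the
profiles differ *between* individuals.  A tiny 2x2 SOM per individual makes
this visible; ``profile_coherence`` turns it into numbers: mean pairwise
Pearson correlation of member profiles within each individual versus mean
pairwise correlation of per-individual mean profiles, compared only across
individuals sharing a sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cluster import scale_rows
from .core_io import ExpressionMatrix, SampleTable, Series, ValidationError

__all__ = ["SomFit", "CoherenceReport", "fit_som_grid", "profile_coherence"]

#: 2x2 grid node coordinates, row-major.
_GRID = np.array([(0, 0), (0, 1), (1, 0), (1, 1)], dtype=float)
_GRID_DIST2 = np.sum(
    (_GRID[:, None, :] - _GRID[None, :, :]) ** 2, axis=-1)


@dataclass
class SomFit:
    """Fitted 2x2 map for one individual's gene profiles."""

    individual_id: str
    genes: list[str]                 # genes actually fitted (non-constant)
    codebook: np.ndarray             # (4, T) node profiles, scaled units
    assignment: dict[str, int]       # gene -> node index 0..3
    occupancy: np.ndarray            # (4,) counts
    quantization_errors: np.ndarray  # per-epoch mean squared distance to BMU
    n_excluded: int = 0              # all-constant genes dropped

    def co_assigned(self, g1: str, g2: str) -> bool:
        return self.assignment[g1] == self.assignment[g2]


def fit_som_grid(matrix: ExpressionMatrix, genes: Sequence[str],
                 individual: str, samples: Sequence[str], seed: int,
                 n_epochs: int = 20) -> SomFit:
    """Batch-Kohonen fit of a 2x2 grid to one individual's scaled profiles.

    Codebook is initialized from the first two principal components of the
    scaled profiles; the Gaussian neighborhood radius decays linearly from
    1 to 0 over the epochs, so the final epochs are plain batch k-means.
    Deterministic for a given seed (the seed only matters for degenerate
    inputs needing jitter).
    """
    genes = list(genes)
    samples = list(samples)
    if not genes:
        raise ValidationError("empty gene set")
    if len(samples) < 3:
        raise ValidationError(
            f"individual {individual!r}: need >=3 samples, got {len(samples)}")
    x = matrix.subset(genes=genes, samples=samples).values
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    n_excluded = int(np.sum(~keep))
    fitted_genes = [g for g, k in zip(genes, keep) if k]
    if not fitted_genes:
        raise ValidationError("all gene profiles constant for this individual")
    z = scale_rows(x[keep])

    rng = np.random.default_rng(seed)
    center = z.mean(axis=0)
    zc = z - center
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    scales = s[:2] / max(np.sqrt(len(fitted_genes) - 1), 1.0)
    dirs = vt[:2] if len(s) >= 2 else np.vstack([vt[0], rng.standard_normal(z.shape[1]) * 1e-3])
    if len(s) >= 2 and s[1] <= 1e-12 * max(s[0], 1.0):
        dirs = np.vstack([dirs[0], rng.standard_normal(z.shape[1]) * 1e-3])
        scales = np.array([scales[0], 1e-3])
    signs = _GRID * 2.0 - 1.0   # node coords mapped to {-1, +1}
    codebook = center + signs @ (dirs * scales[:len(dirs), None])

    qe = np.empty(n_epochs)
    for epoch in range(n_epochs):
        d2 = ((z[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=-1)
        bmu = np.argmin(d2, axis=1)
        radius = 1.0 * (1.0 - epoch / max(n_epochs - 1, 1))
        if radius > 0:
            h = np.exp(-_GRID_DIST2 / (2.0 * radius ** 2))
        else:
            h = np.eye(4)
        w = h[:, bmu]                         # (4, G) node weights per gene
        denom = w.sum(axis=1)
        num = w @ z
        nz = denom > 0
        codebook[nz] = num[nz] / denom[nz, None]
        d2 = ((z[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=-1)
        bmu = np.argmin(d2, axis=1)
        qe[epoch] = float(d2[np.arange(len(bmu)), bmu].mean())

    occupancy = np.bincount(bmu, minlength=4)
    return SomFit(
        individual_id=individual,
        genes=fitted_genes,
        codebook=codebook,
        assignment={g: int(b) for g, b in zip(fitted_genes, bmu)},
        occupancy=occupancy,
        quantization_errors=qe,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

@dataclass
class CoherenceReport:
    """Within/between-individual profile-shape similarity of a gene set."""

    within_by_individual: dict[str, float]
    within: float                    # mean over individuals
    between: float                   # mean pairwise r of individual mean profiles
    n_undefined: int                 # zero-variance profiles excluded
    skipped_individuals: list[str]
    composition_signature: bool


def _mean_pairwise_r(rows: np.ndarray) -> tuple[Optional[float], int]:
    """Mean off-diagonal Pearson r; zero-variance rows are dropped."""
    sd = rows.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int(np.sum(~keep))
    rows = rows[keep]
    if len(rows) < 2:
        return None, dropped
    r = np.corrcoef(rows)
    iu = np.triu_indices(len(rows), k=1)
    return float(r[iu].mean()), dropped


def profile_coherence(matrix: ExpressionMatrix, genes: Sequence[str],
                      sample_table: SampleTable,
                      within_threshold: float = 0.8,
                      between_threshold: float = 0.3) -> CoherenceReport:
    """Quantify the composition signature of a gene set.

    The signature flag is true iff mean within-individual coherence >=
    ``within_threshold`` and between-individual coherence <=
    ``between_threshold``.  Individuals with fewer than 3 time points are
    skipped; between-individual correlations are only computed across
    individuals of the same series (identical sampling grids).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("need >=2 genes for a coherence report")
    by_ind = sample_table.by_individual()
    if len(by_ind) < 2:
        raise ValidationError("need >=2 individuals")

    within: dict[str, float] = {}
    undefined = 0
    skipped: list[str] = []
    mean_profiles: dict[Series, dict[str, np.ndarray]] = {}
    for ind, recs in by_ind.items():
        recs = sorted(recs, key=lambda r: r.recovery_time_h)
        if len(recs) < 3:
            skipped.append(ind)
            continue
        x = matrix.subset(genes=genes, samples=[r.sample_id for r in recs]).values
        r_mean, dropped = _mean_pairwise_r(x)
        undefined += dropped
        if r_mean is not None:
            within[ind] = r_mean
        series = recs[0].series
        z = scale_rows(x)
        mean_profiles.setdefault(series, {})[ind] = z.mean(axis=0)

    between_vals: list[float] = []
    for series, profs in mean_profiles.items():
        inds = sorted(profs)
        for i in range(len(inds)):
            for j in range(i + 1, len(inds)):
                a, b = profs[inds[i]], profs[inds[j]]
                if a.std(ddof=1) > 0 and b.std(ddof=1) > 0:
                    between_vals.append(float(np.corrcoef(a, b)[0, 1]))
                else:
                    undefined += 1

    w = float(np.mean(list(within.values()))) if within else float("nan")
    b = float(np.mean(between_vals)) if between_vals else float("nan")
    flag = bool(np.isfinite(w) and np.isfinite(b)
                and w >= within_threshold and b <= between_threshold)
    return CoherenceReport(
        within_by_individual=within,
        within=w,
        between=b,
        n_undefined=undefined,
        skipped_individuals=skipped,
        composition_signature=flag,
    )
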