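"""Statistical core: mixed models, permutation Fs tests, q-values.

Model per gene: y = X beta + Z u + e with a single random intercept per
individual, u ~ N(0, sigma_u^2 I), e ~ N(0, sigma_e^2 I).  Estimation is
REML, profiled over the variance ratio theta = sigma_u^2 / sigma_e^2; for a
single random intercept the generalized least squares algebra reduces to
per-individual block sums (Sherman-Morrison within blocks), which keeps the
per-gene fit cheap enough to run over thousands of genes.

Differential expression uses an F-like statistic whose per-gene residual
variance is replaced by a James-Stein-shrunken estimate on the log scale
(shrinkage toward the across-gene mean, with the chi-square bias of the log
variance removed), and permutation p-values pooled across genes: condition
labels are permuted within each individual so the repeated-measures
blocking is preserved; factors that are constant within an individual
(treatment arm) are instead permuted across individuals within a series.

False-discovery control follows the smoother-based null-proportion
estimate: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid,
a cubic least-squares smooth evaluated at the largest lambda, and step-up
monotonized q-values (pi0 = 1 reduces exactly to Benjamini-Hochberg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .core_io import (
    Dose,
    ExpressionMatrix,
    GeneSet,
    Provenance,
    SampleRecord,
    SampleTable,
    Series,
    ValidationError,
)

log = logging.getLogger("confounderscan.stats")

__all__ = [
    "MixedModelFit",
    "MixedModelCollection",
    "FsTestResult",
    "QValueResult",
    "AnovaDecomposition",
    "biopsy_level",
    "dose_time_level",
    "within_arm_contrasts",
    "between_arm_contrasts",
    "fit_mixed_model",
    "fit_mixed_model_matrix",
    "fs_permutation_test",
    "estimate_qvalues",
    "run_contrast_scan",
    "anova_decomposition",
]

_THETA_MAX = 1.0e6
_GOLDEN_TOL = 1.0e-11


# ---------------------------------------------------------------------------
# factor levels
# ---------------------------------------------------------------------------

def biopsy_level(rec: SampleRecord) -> str:
    if rec.biopsy_order is None:
        raise ValidationError(
            f"sample {rec.sample_id!r} has no biopsy order; relabel first")
    return f"b{rec.biopsy_order}"


def dose_time_level(rec: SampleRecord) -> str:
    """Group-means cell label: series | treated flag | recovery time."""
    arm = "T" if rec.treated else "U"
    return f"{rec.series.value}|{arm}|t{rec.recovery_time_h:g}"


def within_arm_contrasts(samples: SampleTable) -> list[tuple[str, str]]:
    """Each recovery time vs t0 within every (series, treated) arm present."""
    out = []
    seen = set()
    for series in (Series.EARLY, Series.LATE):
        for treated in (False, True):
            arm = samples.filter(series=series, treated=treated)
            times = sorted({r.recovery_time_h for r in arm})
            if 0.0 not in times:
                continue
            ref = dose_time_level(next(r for r in arm if r.recovery_time_h == 0.0))
            for t in times:
                if t == 0.0:
                    continue
                lvl = dose_time_level(next(r for r in arm if r.recovery_time_h == t))
                if (ref, lvl) not in seen:
                    seen.add((ref, lvl))
                    out.append((ref, lvl))
    return out


def between_arm_contrasts(samples: SampleTable) -> list[tuple[str, str]]:
    """Treated vs time-matched untreated within each series."""
    out = []
    for series in (Series.EARLY, Series.LATE):
        untr = samples.filter(series=series, treated=False)
        trt = samples.filter(series=series, treated=True)
        t_u = {r.recovery_time_h for r in untr}
        t_t = {r.recovery_time_h for r in trt}
        for t in sorted(t_u & t_t):
            u = dose_time_level(next(r for r in untr if r.recovery_time_h == t))
            v = dose_time_level(next(r for r in trt if r.recovery_time_h == t))
            out.append((u, v))
    return out


def _dummies(labels: Sequence[str],
             levels: Optional[Sequence[str]] = None) -> tuple[np.ndarray, list[str]]:
    if levels is None:
        levels = sorted(set(labels))
    idx = {lv: j for j, lv in enumerate(levels)}
    X = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        X[i, idx[lab]] = 1.0
    return X, list(levels)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

class _GlsWorkspace:
    """Precomputed design quantities for single-random-intercept GLS."""

    def __init__(self, X: np.ndarray, blocks: np.ndarray):
        self.X = X
        self.blocks = blocks
        self.n, self.p = X.shape
        self.n_ind = int(blocks.max()) + 1
        self.n_i = np.bincount(blocks, minlength=self.n_ind).astype(float)
        self.XtX = X.T @ X
        S = np.zeros((self.n_ind, self.p))
        np.add.at(S, blocks, X)
        self.S = S
        if np.linalg.matrix_rank(self.XtX) < self.p:
            # identify confounded columns for the error message
            _, r = np.linalg.qr(X)
            bad = [j for j in range(self.p) if abs(r[j, j]) < 1e-10]
            raise ValidationError(f"singular fixed design (columns {bad})")

    def block_sums(self, y: np.ndarray) -> np.ndarray:
        t = np.zeros(self.n_ind)
        np.add.at(t, self.blocks, y)
        return t

    def gls(self, theta: float, Xty: np.ndarray, t: np.ndarray, yty: float):
        c = theta / (1.0 + self.n_i * theta)
        A = self.XtX - self.S.T @ (c[:, None] * self.S)
        b = Xty - self.S.T @ (c * t)
        beta = np.linalg.solve(A, b)
        q = yty - float(c @ np.square(t))
        rss = q - float(b @ beta)
        return A, beta, max(rss, 0.0), c

    def reml_neg2ll(self, theta: float, Xty: np.ndarray, t: np.ndarray,
                    yty: float) -> float:
        A, _, rss, _ = self.gls(theta, Xty, t, yty)
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0 or rss <= 0:
            return np.inf
        return (float(np.sum(np.log1p(self.n_i * theta)))
                + logdet + (self.n - self.p) * np.log(rss))


def _golden_min(f: Callable[[float], float], lo: float, hi: float,
                tol: float = _GOLDEN_TOL) -> float:
    """Golden-section minimization on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol * (1.0 + abs(a) + abs(b)):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _reml_theta(ws: _GlsWorkspace, Xty: np.ndarray, t: np.ndarray,
                yty: float) -> float:
    """Profile-REML estimate of the variance ratio, truncated at 0."""
    f = lambda th: ws.reml_neg2ll(th, Xty, t, yty)
    grid = np.concatenate([[0.0], np.logspace(-4, 6, 41)])
    vals = np.array([f(th) for th in grid])
    k = int(np.nanargmin(vals))
    if k == 0:
        hi = grid[1]
        th = _golden_min(f, 0.0, hi)
        return th if f(th) < f(0.0) else 0.0
    lo = grid[k - 1]
    hi = grid[min(k + 1, len(grid) - 1)]
    # refine in log space for scale invariance
    g = lambda u: f(np.exp(u))
    u = _golden_min(g, np.log(max(lo, 1e-12)), np.log(hi))
    th = float(np.exp(u))
    return th if f(th) <= f(0.0) else 0.0


def _is_balanced_oneway(ws: _GlsWorkspace) -> bool:
    if ws.p != 1:
        return False
    col = ws.X[:, 0]
    return np.allclose(col, col[0]) and np.all(ws.n_i == ws.n_i[0])


@dataclass
class MixedModelFit:
    """One gene's mixed-model fit."""

    level_names: list[str]
    coefficients: np.ndarray         # fixed-effect (level-mean) estimates
    individual_ids: list[str]
    individual_coefs: np.ndarray     # BLUPs of the random intercepts
    sigma_u2: float
    sigma_e2: float
    theta: float
    df_resid: int


@dataclass
class MixedModelCollection:
    """Vectorized mixed-model fits for many genes on one design."""

    gene_ids: list[str]
    level_names: list[str]
    individual_ids: list[str]
    beta: np.ndarray                 # (G, p)
    blups: np.ndarray                # (G, I)
    sigma_u2: np.ndarray             # (G,)
    sigma_e2: np.ndarray             # (G,)
    theta: np.ndarray                # (G,)
    df_resid: int

    def individual_coef_map(self) -> dict[str, np.ndarray]:
        return {g: self.blups[i] for i, g in enumerate(self.gene_ids)}

    def fit_for(self, gene: str) -> MixedModelFit:
        i = self.gene_ids.index(gene)
        return MixedModelFit(
            level_names=self.level_names,
            coefficients=self.beta[i],
            individual_ids=self.individual_ids,
            individual_coefs=self.blups[i],
            sigma_u2=float(self.sigma_u2[i]),
            sigma_e2=float(self.sigma_e2[i]),
            theta=float(self.theta[i]),
            df_resid=self.df_resid,
        )


def _prepare_design(samples: SampleTable, fixed: str):
    if fixed == "biopsy":
        labels = [biopsy_level(r) for r in samples]
    elif fixed == "dose_time":
        labels = [dose_time_level(r) for r in samples]
    elif fixed == "intercept":
        labels = ["mu"] * len(samples)
    else:
        raise ValidationError(f"unknown fixed factor spec {fixed!r}")
    X, levels = _dummies(labels)
    inds = samples.individual_ids
    ind_index = {v: k for k, v in enumerate(inds)}
    blocks = np.array([ind_index[r.individual_id] for r in samples])
    return X, levels, blocks, inds


def fit_mixed_model_matrix(matrix: ExpressionMatrix, samples: SampleTable,
                           fixed: str = "dose_time",
                           random_individual: bool = True) -> MixedModelCollection:
    """Fit the per-gene mixed model for every gene in the matrix.

    With ``random_individual=False`` this is ordinary least squares with
    zero individual coefficients.
    """
    X, levels, blocks, inds = _prepare_design(samples, fixed)
    Y = matrix.sample_cols(samples.sample_ids)
    ws = _GlsWorkspace(X, blocks)
    G = matrix.n_genes
    n, p = ws.n, ws.p
    if random_individual and ws.n_ind < 2:
        raise ValidationError("random individual term needs >=2 individuals")
    df = n - p
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")

    beta = np.empty((G, p))
    blups = np.zeros((G, ws.n_ind))
    s_u2 = np.zeros(G)
    s_e2 = np.empty(G)
    thetas = np.zeros(G)

    if not random_individual:
        XtY = X.T @ Y.T                       # (p, G)
        beta = np.linalg.solve(ws.XtX, XtY).T
        resid = Y - beta @ X.T
        s_e2 = np.sum(resid ** 2, axis=1) / df
        return MixedModelCollection(matrix.gene_ids, levels, inds, beta, blups,
                                    s_u2, s_e2, thetas, df)

    balanced = _is_balanced_oneway(ws)
    for i in range(G):
        y = Y[i]
        Xty = X.T @ y
        t = ws.block_sums(y)
        yty = float(y @ y)
        if balanced:
            th, su, se = _balanced_oneway_closed_form(ws, y, t)
        else:
            th = _reml_theta(ws, Xty, t, yty)
            _, b, rss, _ = ws.gls(th, Xty, t, yty)
            se = rss / df
            su = th * se
        _, b, rss, c = ws.gls(th, Xty, t, yty)
        beta[i] = b
        blups[i] = c * (t - ws.S @ b)
        s_u2[i] = su
        s_e2[i] = se if balanced else rss / df
        thetas[i] = th
    return MixedModelCollection(matrix.gene_ids, levels, inds, beta, blups,
                                s_u2, s_e2, thetas, df)


def _balanced_oneway_closed_form(ws: _GlsWorkspace, y: np.ndarray,
                                 t: np.ndarray) -> tuple[float, float, float]:
    """ANOVA/REML closed form for a balanced one-way random-effects layout."""
    n0 = ws.n_i[0]
    I = ws.n_ind
    gmean = y.mean()
    group_means = t / n0
    ssb = float(n0 * np.sum((group_means - gmean) ** 2))
    ssw = float(np.sum((y - group_means[ws.blocks]) ** 2))
    msb = ssb / (I - 1)
    msw = ssw / (ws.n - I)
    su = max(0.0, (msb - msw) / n0)
    if su > 0:
        se = msw
    else:
        se = float(np.sum((y - gmean) ** 2)) / (ws.n - 1)
    theta = su / se if se > 0 else 0.0
    return theta, su, se


def fit_mixed_model(y: np.ndarray, samples: SampleTable, fixed: str = "dose_time",
                    random_individual: bool = True) -> MixedModelFit:
    """Single-gene convenience wrapper around :func:`fit_mixed_model_matrix`."""
    y = np.asarray(y, dtype=float)
    if y.shape != (len(samples),):
        raise ValidationError(
            f"y has shape {y.shape}, expected ({len(samples)},)")
    m = ExpressionMatrix(["gene"], samples.sample_ids, y[None, :])
    coll = fit_mixed_model_matrix(m, samples, fixed=fixed,
                                  random_individual=random_individual)
    return coll.fit_for("gene")


# ---------------------------------------------------------------------------
# shrinkage Fs statistic and permutation test
# ---------------------------------------------------------------------------

def shrink_variances(sigma2: np.ndarray, df: float) -> np.ndarray:
    """James-Stein shrinkage of log residual variances toward their mean.

    The log variances are shifted by the chi-square bias of the log
    variance, digamma(df/2) - log(df/2), shrunk toward their mean with the
    positive-part James-Stein factor (sampling variance trigamma(df/2)),
    and shifted back; a gene at the across-gene mean, or any input with all
    variances equal, is returned unchanged.
    """
    sigma2 = np.maximum(np.asarray(sigma2, dtype=float), 1e-300)
    G = sigma2.size
    bias = digamma(df / 2.0) - np.log(df / 2.0)
    x = np.log(sigma2) - bias
    if G < 4:
        return sigma2.copy()
    xbar = x.mean()
    ss = float(np.sum((x - xbar) ** 2))
    nu = float(polygamma(1, df / 2.0))
    factor = max(0.0, 1.0 - (G - 3.0) * nu / ss) if ss > 0 else 0.0
    return np.exp(xbar + factor * (x - xbar) + bias)


@dataclass
class FsTestResult:
    """Per-gene results of one contrast's permutation Fs test."""

    contrast: tuple[str, str]
    gene_ids: list[str]
    contrast_ms: np.ndarray        # contrast mean square
    sigma2_raw: np.ndarray
    sigma2_shrunk: np.ndarray
    fs: np.ndarray
    pvalues: np.ndarray
    qvalues: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "gene_id": self.gene_ids,
            "contrast_ms": self.contrast_ms,
            "sigma2_raw": self.sigma2_raw,
            "sigma2_shrunk": self.sigma2_shrunk,
            "Fs": self.fs,
            "p": self.pvalues,
        }
        if self.qvalues is not None:
            d["q"] = self.qvalues
        return pd.DataFrame(d)


def _compose(between: Optional[np.ndarray], within: np.ndarray) -> np.ndarray:
    if between is None:
        return within.copy()
    return np.char.add(np.char.add(between.astype("U32"), "|"),
                       within.astype("U32"))


def _fs_eval_gls(Y, ws, Xty_all, t_all, yty_all, theta, contrast_vecs):
    """CMS per contrast and raw variances under per-gene REML GLS weights."""
    G = Y.shape[0]
    n, p = ws.n, ws.p
    n_i = ws.n_i
    C = theta[:, None] / (1.0 + n_i[None, :] * theta[:, None])   # (G, I)
    A = ws.XtX[None] - np.einsum("ip,gi,iq->gpq", ws.S, C, ws.S)  # (G,p,p)
    b = Xty_all - np.einsum("gi,ip->gp", C * t_all, ws.S)         # (G,p)
    q = yty_all - np.sum(C * t_all ** 2, axis=1)
    K = len(contrast_vecs)
    rhs = np.concatenate([b[:, :, None],
                          np.broadcast_to(np.stack(contrast_vecs, axis=1)[None],
                                          (G, p, K))], axis=2)
    sol = np.linalg.solve(A, rhs)
    betas = sol[:, :, 0]
    rss = np.maximum(q - np.einsum("gp,gp->g", b, betas), 0.0)
    df = n - p
    sigma2 = rss / df
    cms = np.empty((G, K))
    for k, c in enumerate(contrast_vecs):
        chat = betas @ c
        varfac = np.einsum("p,gp->g", c, sol[:, :, 1 + k])
        cms[:, k] = chat ** 2 / np.maximum(varfac, 1e-300)
    return cms, sigma2, df


def _fs_eval_shared(Y, ws, Xty_all, t_all, yty_all, c_i, contrast_vecs):
    """CMS and raw variances with gene-independent block weights.

    ``c_i = 0`` is plain OLS; ``c_i = 1/n_i`` projects out per-individual
    means exactly (the theta -> infinity limit of the random intercept), so
    results are invariant to adding any constant per individual.  The
    projected normal matrix may be singular (block means alias the
    intercept direction of the level dummies); Moore-Penrose inversion
    yields the unique values of all estimable contrasts.
    """
    n, p = ws.n, ws.p
    A = ws.XtX - ws.S.T @ (c_i[:, None] * ws.S)
    b = Xty_all - (c_i * t_all) @ ws.S                   # (G, p)
    q = yty_all - t_all ** 2 @ c_i
    pinvA = np.linalg.pinv(A, rcond=1e-10)
    rank_A = int(np.linalg.matrix_rank(A, tol=1e-8))
    betas = b @ pinvA.T
    rss = np.maximum(q - np.einsum("gp,gp->g", b, betas), 0.0)
    absorbed = int(np.any(c_i > 0)) * ws.n_ind
    df = n - absorbed - rank_A
    sigma2 = rss / df
    K = len(contrast_vecs)
    cms = np.empty((Y.shape[0], K))
    for k, c in enumerate(contrast_vecs):
        chat = betas @ c
        varfac = float(c @ pinvA @ c)
        cms[:, k] = chat ** 2 / max(varfac, 1e-300)
    return cms, sigma2, df


def _fs_scan(Y: np.ndarray, gene_ids: list[str], blocks: np.ndarray,
             within: np.ndarray, between: Optional[np.ndarray],
             series_of_ind: np.ndarray, contrasts: Sequence[tuple[str, str]],
             n_perm: int, seed: int, mode: str,
             pool: bool = True) -> list[FsTestResult]:
    """Shared engine: observed Fs plus pooled permutation null for contrasts.

    ``mode``: "ols" (no individual term), "absorb" (individual as exact
    blocking projection; within-individual contrasts only) or "gls"
    (REML random intercept, weights estimated once on the observed data).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if mode not in ("ols", "absorb", "gls"):
        raise ValidationError(f"unknown mode {mode!r}")
    labels = _compose(between[blocks] if between is not None else None, within)
    levels = sorted(set(labels.tolist()))
    for a, b in contrasts:
        if a not in levels or b not in levels:
            raise ValidationError(f"contrast level {a if a not in levels else b!r} "
                                  f"not present in the design")
    lvl_index = {lv: j for j, lv in enumerate(levels)}
    p = len(levels)
    contrast_vecs = []
    for a, b in contrasts:
        c = np.zeros(p)
        c[lvl_index[b]] = 1.0
        c[lvl_index[a]] = -1.0
        contrast_vecs.append(c)

    G, n = Y.shape
    n_ind = int(blocks.max()) + 1

    def build_ws(lab):
        X, _ = _dummies(lab, levels)
        return _GlsWorkspace(X, blocks)

    ws = build_ws(labels)
    t_all = np.zeros((G, n_ind))
    np.add.at(t_all.T, blocks, Y.T)          # block sums per gene
    yty_all = np.einsum("gn,gn->g", Y, Y)

    theta = np.zeros(G)
    if mode == "gls":
        for i in range(G):
            y = Y[i]
            theta[i] = _reml_theta(ws, ws.X.T @ y, t_all[i], float(yty_all[i]))
    c_shared = (1.0 / ws.n_i) if mode == "absorb" else np.zeros(ws.n_ind)

    def evaluate(lab_ws):
        Xty = (lab_ws.X.T @ Y.T).T            # (G, p)
        if mode == "gls":
            cms, sigma2, df = _fs_eval_gls(Y, lab_ws, Xty, t_all, yty_all,
                                           theta, contrast_vecs)
        else:
            cms, sigma2, df = _fs_eval_shared(Y, lab_ws, Xty, t_all, yty_all,
                                              c_shared, contrast_vecs)
        shr = shrink_variances(sigma2, df)
        return cms / shr[:, None], sigma2, shr

    fs_obs, sigma2_obs, shr_obs = evaluate(ws)

    rng = np.random.default_rng(seed)
    sample_idx_by_ind = [np.flatnonzero(blocks == i) for i in range(n_ind)]
    counts = np.zeros((G, len(contrasts)), dtype=np.int64)
    order = [np.argsort(fs_obs[:, k]) for k in range(len(contrasts))]
    sorted_obs = [fs_obs[order[k], k] for k in range(len(contrasts))]

    for _ in range(n_perm):
        w_perm = within.copy()
        for idx in sample_idx_by_ind:
            w_perm[idx] = within[idx][rng.permutation(len(idx))]
        if between is not None:
            b_perm = between.copy()
            for s in np.unique(series_of_ind):
                ids = np.flatnonzero(series_of_ind == s)
                b_perm[ids] = between[ids][rng.permutation(len(ids))]
            lab = _compose(b_perm[blocks], w_perm)
        else:
            lab = _compose(None, w_perm)
        fs_perm, _, _ = evaluate(build_ws(lab))
        for k in range(len(contrasts)):
            if pool:
                null_vals = np.sort(fs_perm[:, k])
                exceed = G - np.searchsorted(null_vals, sorted_obs[k], side="left")
                counts[order[k], k] += exceed
            else:
                counts[:, k] += (fs_perm[:, k] >= fs_obs[:, k]).astype(np.int64)

    denom = 1 + (G * n_perm if pool else n_perm)
    pvals = (1 + counts) / denom

    results = []
    for k, contrast in enumerate(contrasts):
        results.append(FsTestResult(
            contrast=tuple(contrast),
            gene_ids=list(gene_ids),
            contrast_ms=fs_obs[:, k] * shr_obs,
            sigma2_raw=sigma2_obs,
            sigma2_shrunk=shr_obs,
            fs=fs_obs[:, k],
            pvalues=pvals[:, k],
        ))
    return results


def _restrict_to_contrast(samples: SampleTable, level_of: Callable[[SampleRecord], str],
                          contrast: tuple[str, str]) -> tuple[SampleTable, bool]:
    """Drop individuals lacking a contrast level (within-individual contrasts).

    Returns (table, is_within).  If the rule would drop every individual
    the contrast is between-individual and all samples are kept.
    """
    keep = []
    for ind, recs in samples.by_individual().items():
        levels = {level_of(r) for r in recs}
        if contrast[0] in levels and contrast[1] in levels:
            keep.append(ind)
        else:
            log.warning("individual %s lacks a level of contrast %s; excluded",
                        ind, contrast)
    if not keep:
        lvl_all = {level_of(r) for r in samples}
        if contrast[0] in lvl_all and contrast[1] in lvl_all:
            return samples, False  # between-individual contrast
        raise ValidationError(
            f"no individual carries both levels of contrast {contrast}")
    return samples.filter(individuals=keep), True


def fs_permutation_test(matrix: ExpressionMatrix, samples: SampleTable,
                        contrast: tuple[str, str], n_perm: int, seed: int,
                        random_individual: bool = True,
                        factor: str = "biopsy",
                        pool: bool = True) -> FsTestResult:
    """Permutation Fs test of one contrast (default: biopsy-order levels).

    Condition labels are permuted within each individual; the pooled null
    across genes gives the p-values.  Individuals lacking a contrast level
    are excluded (with a warning) unless the contrast is between-individual.

    With ``random_individual=True`` the individual term enters as an exact
    blocking projection for within-individual contrasts (invariant to any
    per-mouse offset) and as a REML random intercept for between-individual
    contrasts, where between-mouse information is needed.
    """
    level_of = biopsy_level if factor == "biopsy" else dose_time_level
    if factor not in ("biopsy", "dose_time"):
        raise ValidationError(f"unknown factor {factor!r}")
    sub, is_within = _restrict_to_contrast(samples, level_of, contrast)
    mode = ("absorb" if is_within else "gls") if random_individual else "ols"
    Y = matrix.sample_cols(sub.sample_ids)
    inds = sub.individual_ids
    ind_index = {v: k for k, v in enumerate(inds)}
    blocks = np.array([ind_index[r.individual_id] for r in sub])
    series_of_ind = np.array(
        [sub.by_individual()[i][0].series.value for i in inds])
    if factor == "biopsy":
        within = np.array([biopsy_level(r) for r in sub])
        between = None
    else:
        within = np.array([f"t{r.recovery_time_h:g}" for r in sub])
        between = np.array(
            [f"{sub.by_individual()[i][0].series.value}|"
             f"{'T' if sub.by_individual()[i][0].treated else 'U'}"
             for i in inds])
    (res,) = _fs_scan(Y, matrix.gene_ids, blocks, within, between,
                      series_of_ind, [contrast], n_perm, seed,
                      mode, pool=pool)
    return res


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

@dataclass
class QValueResult:
    pi0: float
    lambda_grid: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray


def estimate_qvalues(p: np.ndarray, lambda_grid: Optional[np.ndarray] = None,
                     pi0: Optional[float] = None) -> QValueResult:
    """Smoother-based q-values.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda))
    with a cubic least-squares smooth evaluated at the largest lambda
    (forced pi0, e.g. 1.0, reduces the procedure to Benjamini-Hochberg).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value collection")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.91, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) <= 0) or lambda_grid.max() >= 1:
        raise ValidationError("lambda grid must be strictly increasing, < 1")

    if pi0 is None:
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambda_grid])
        if len(lambda_grid) >= 4:
            coef = np.polyfit(lambda_grid, pi0_lam, deg=3)
            pi0_hat = float(np.polyval(coef, lambda_grid.max()))
        else:
            pi0_hat = float(pi0_lam[-1])
        pi0_hat = min(pi0_hat, 1.0)
        pi0_hat = max(pi0_hat, 1.0 / m)
    else:
        pi0_hat = float(pi0)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ranked = pi0_hat * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return QValueResult(pi0=pi0_hat, lambda_grid=lambda_grid, pvalues=p,
                        qvalues=q)


# ---------------------------------------------------------------------------
# contrast scans
# ---------------------------------------------------------------------------

def run_contrast_scan(matrix: ExpressionMatrix, samples: SampleTable,
                      contrasts: Sequence[tuple[str, str]],
                      random_individual: bool, q_threshold: float,
                      n_perm: int = 300, seed: int = 0,
                      ) -> tuple[dict[tuple[str, str], GeneSet],
                                 dict[tuple[str, str], FsTestResult]]:
    """Fs-test every contrast on dose-time group means; DEG = q <= threshold.

    Returns (per-contrast DEG gene sets, per-contrast full result tables).
    """
    valid = set(within_arm_contrasts(samples)) | set(between_arm_contrasts(samples))
    for c in contrasts:
        if tuple(c) not in valid:
            raise ValidationError(f"invalid contrast {c} for this design")
    deg_sets: dict[tuple[str, str], GeneSet] = {}
    tables: dict[tuple[str, str], FsTestResult] = {}
    for k, contrast in enumerate(contrasts):
        res = fs_permutation_test(
            matrix, samples, tuple(contrast), n_perm=n_perm,
            seed=int(np.random.default_rng([seed, k]).integers(2 ** 31)),
            random_individual=random_individual, factor="dose_time")
        res.qvalues = estimate_qvalues(res.pvalues).qvalues
        hits = [g for g, q in zip(res.gene_ids, res.qvalues) if q <= q_threshold]
        deg_sets[tuple(contrast)] = GeneSet(
            name=f"DEG {contrast[0]} vs {contrast[1]}",
            provenance=Provenance.DEG,
            genes=tuple(hits),
            description=f"q <= {q_threshold}, "
                        f"{'with' if random_individual else 'without'} individual term",
            empty_allowed=True,
        )
        tables[tuple(contrast)] = res
    return deg_sets, tables


# ---------------------------------------------------------------------------
# additive ANOVA decomposition
# ---------------------------------------------------------------------------

@dataclass
class AnovaDecomposition:
    """Y = mu + individual effect + dose-time effect + residual (per gene)."""

    gene_ids: list[str]
    sample_ids: list[str]
    individual_ids: list[str]
    cell_names: list[str]
    mu: np.ndarray                  # (G,)
    individual_effects: np.ndarray  # (G, I), sum-to-zero over individuals
    cell_effects: np.ndarray        # (G, C), sum-to-zero over cells
    residuals: np.ndarray           # (G, n)
    ind_of_sample: np.ndarray
    cell_of_sample: np.ndarray

    def fitted(self) -> np.ndarray:
        return (self.mu[:, None]
                + self.individual_effects[:, self.ind_of_sample]
                + self.cell_effects[:, self.cell_of_sample])

    def component_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "individual": pd.DataFrame(self.individual_effects,
                                       index=self.gene_ids,
                                       columns=self.individual_ids),
            "cell": pd.DataFrame(self.cell_effects, index=self.gene_ids,
                                 columns=self.cell_names),
            "residual": pd.DataFrame(self.residuals, index=self.gene_ids,
                                     columns=self.sample_ids),
        }


def anova_decomposition(matrix: ExpressionMatrix, samples: SampleTable,
                        tol: float = 1e-12, max_iter: int = 2000
                        ) -> AnovaDecomposition:
    """Backfitted least-squares additive decomposition.

    Both effect blocks are centered (sum-to-zero over levels) every sweep;
    the residual is exactly Y minus the assembled components, so the
    decomposition always reproduces Y.
    """
    inds = samples.individual_ids
    cells = sorted({dose_time_level(r) for r in samples})
    if len(inds) < 2 or len(cells) < 2:
        raise ValidationError("need >=2 individuals and >=2 dose-time cells")
    ind_index = {v: k for k, v in enumerate(inds)}
    cell_index = {v: k for k, v in enumerate(cells)}
    iof = np.array([ind_index[r.individual_id] for r in samples])
    cof = np.array([cell_index[dose_time_level(r)] for r in samples])
    n_i = np.bincount(iof, minlength=len(inds)).astype(float)
    n_c = np.bincount(cof, minlength=len(cells)).astype(float)

    Y = matrix.sample_cols(samples.sample_ids)
    G = matrix.n_genes
    mu = Y.mean(axis=1)
    alpha = np.zeros((G, len(inds)))
    gamma = np.zeros((G, len(cells)))

    for _ in range(max_iter):
        r = Y - mu[:, None] - gamma[:, cof]
        alpha_new = np.zeros_like(alpha)
        np.add.at(alpha_new.T, iof, r.T)
        alpha_new /= n_i[None, :]
        alpha_new -= alpha_new.mean(axis=1, keepdims=True)

        r = Y - mu[:, None] - alpha_new[:, iof]
        gamma_new = np.zeros_like(gamma)
        np.add.at(gamma_new.T, cof, r.T)
        gamma_new /= n_c[None, :]
        gamma_new -= gamma_new.mean(axis=1, keepdims=True)

        mu_new = (Y - alpha_new[:, iof] - gamma_new[:, cof]).mean(axis=1)
        delta = max(np.max(np.abs(alpha_new - alpha)),
                    np.max(np.abs(gamma_new - gamma)),
                    np.max(np.abs(mu_new - mu)))
        alpha, gamma, mu = alpha_new, gamma_new, mu_new
        if delta < tol:
            break

    resid = Y - (mu[:, None] + alpha[:, iof] + gamma[:, cof])
    return AnovaDecomposition(
        gene_ids=list(matrix.gene_ids),
        sample_ids=samples.sample_ids,
        individual_ids=inds,
        cell_names=cells,
        mu=mu,
        individual_effects=alpha,
        cell_effects=gamma,
        residuals=resid,
        ind_of_sample=iof,
        cell_of_sample=cof,
    )
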