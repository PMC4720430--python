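"""Variance screening, Ward clustering and PCA gene-subset discovery.

The first diagnostic stage ranks genes by their standard deviation over the
untreated wild-type samples, keeps the top-n most variable, and clusters
them with Ward's method so that tight co-expression blocks (cell-type
composition clusters, time-of-day clusters) become visible.  Seeded cluster
extraction formalizes "find the marker gene in the heatmap and take its
small cluster"; PCA over genes provides the complementary subset view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core_io import ExpressionMatrix, GeneSet, Provenance, ValidationError

__all__ = [
    "VarianceRanking",
    "Dendrogram",
    "PcaScores",
    "ScoreRule",
    "top_variable_genes",
    "ward_cluster",
    "extract_seeded_cluster",
    "pca_scores",
    "pca_gene_subsets",
    "scale_rows",
]


def scale_rows(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center each row and scale to unit SD; constant rows become all-zero."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    out = x - mu
    nz = sd[:, 0] > 0
    out[nz] /= sd[nz]
    return out


# ---------------------------------------------------------------------------
# variance ranking
# ---------------------------------------------------------------------------

@dataclass
class VarianceRanking:
    """Per-gene SD over a declared sample subset, ranked high to low."""

    gene_ids: list[str]          # ranked: index 0 = most variable
    sd: dict[str, float]
    sample_ids: list[str]
    top_n: int

    @property
    def top_genes(self) -> tuple[str, ...]:
        return tuple(self.gene_ids[: self.top_n])

    def rank_of(self, gene: str) -> int:
        """1-based rank (1 = most variable)."""
        return self.gene_ids.index(gene) + 1

    def sd_of(self, gene: str) -> float:
        return self.sd[gene]


def top_variable_genes(matrix: ExpressionMatrix, samples: Sequence[str],
                       n: int) -> VarianceRanking:
    """Rank genes by SD (denominator n-1) over exactly the given samples.

    Ties are broken by gene-ID lexicographic order for reproducibility.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples to compute an SD")
    if not 1 <= n <= matrix.n_genes:
        raise ValidationError(
            f"top-n {n} outside 1..{matrix.n_genes} genes")
    x = matrix.sample_cols(samples)
    sd = x.std(axis=1, ddof=1)
    order = sorted(range(matrix.n_genes),
                   key=lambda i: (-sd[i], matrix.gene_ids[i]))
    ranked = [matrix.gene_ids[i] for i in order]
    return VarianceRanking(
        gene_ids=ranked,
        sd={matrix.gene_ids[i]: float(sd[i]) for i in range(matrix.n_genes)},
        sample_ids=samples,
        top_n=n,
    )


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Binary Ward merge tree over genes.

    ``merges`` follows the scipy linkage convention (node ids 0..n-1 are
    leaves, node n+k is created by merge k) but heights are on the
    within-cluster sum-of-squares increase scale (dSSE), not scipy's
    root-mean form.  ``leaf_order`` places, at every internal node, the
    child with the smaller mean expression first.
    """

    genes: list[str]
    merges: np.ndarray           # (n-1, 2) int children ids
    heights: np.ndarray          # (n-1,) dSSE merge costs
    leaf_order: list[str]
    _members: list[frozenset[str]]  # per node id (leaves then internal)

    @property
    def n_leaves(self) -> int:
        return len(self.genes)

    def members(self, node: int) -> frozenset[str]:
        return self._members[node]

    def node_height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return float(self.heights[node - self.n_leaves])


def ward_cluster(matrix: ExpressionMatrix, genes: Sequence[str],
                 scale: bool = True) -> Dendrogram:
    """Agglomerative Ward clustering of gene profiles.

    Profiles are per-gene centered and unit-SD scaled by default (the
    comparison is between profile shapes); distances are Euclidean.  Merge
    heights are reported as the increase in within-cluster sum of squares.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes to cluster")
    x = matrix.gene_rows(genes)
    if scale:
        x = scale_rows(x)
    z = linkage(x, method="ward")
    merges = z[:, :2].astype(int)
    heights = np.square(z[:, 2]) / 2.0  # scipy height = sqrt(2 * dSSE)

    n = len(genes)
    members: list[frozenset[str]] = [frozenset((g,)) for g in genes]
    for a, b in merges:
        members.append(members[a] | members[b])

    # leaf order: smaller-mean child first at every internal node
    gene_means = matrix.gene_rows(genes).mean(axis=1)
    node_mean = list(gene_means)
    node_size: list[int] = [1] * n
    for a, b in merges:
        sz = node_size[a] + node_size[b]
        node_mean.append((node_mean[a] * node_size[a]
                          + node_mean[b] * node_size[b]) / sz)
        node_size.append(sz)

    order: list[str] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(genes[node])
            continue
        a, b = merges[node - n]
        first, second = (a, b) if (node_mean[a], a) <= (node_mean[b], b) else (b, a)
        stack.append(second)   # LIFO: push second so first is emitted first
        stack.append(first)
    return Dendrogram(genes=genes, merges=merges, heights=heights,
                      leaf_order=order, _members=members)


def extract_seeded_cluster(dendro: Dendrogram, seeds: Sequence[str],
                           max_size: int, name: str = "seeded",
                           provenance: Provenance = Provenance.SC) -> GeneSet:
    """Member set of the lowest dendrogram node containing all seeds.

    A single seed returns its first (smallest) non-leaf ancestor.  If the
    minimal node exceeds ``max_size`` it is returned anyway, flagged
    oversize.
    """
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValidationError("no seed genes given")
    leafset = set(dendro.genes)
    for s in seeds:
        if s not in leafset:
            raise ValidationError(f"seed gene {s!r} is not a leaf of the dendrogram")
    need = set(seeds)
    n = dendro.n_leaves
    best: Optional[int] = None
    for k in range(n - 1):  # merges are height-ordered; first hit is minimal
        node = n + k
        mem = dendro.members(node)
        if need <= mem and len(mem) > 1:
            best = node
            break
    if best is None:  # cannot happen: root contains everything
        best = 2 * n - 2
    mem = dendro.members(best)
    ordered = [g for g in dendro.leaf_order if g in mem]
    return GeneSet(
        name=name,
        provenance=provenance,
        genes=tuple(ordered),
        description=f"seeded by {','.join(seeds)}",
        oversize=len(mem) > max_size,
    )


# ---------------------------------------------------------------------------
# PCA gene subsets
# ---------------------------------------------------------------------------

@dataclass
class PcaScores:
    genes: list[str]
    scores: np.ndarray             # (G, k) component scores of genes
    loadings: np.ndarray           # (k, S) sample loadings
    explained_variance: np.ndarray  # (k,) eigenvalues of the sample covariance


@dataclass(frozen=True)
class ScoreRule:
    """One subset clause: sign/threshold constraints on PC1/PC2 scores.

    ``constraints`` is a sequence of (component, op, threshold) with
    component in {1, 2} and op in {">", ">=", "<", "<="}.
    """

    name: str
    constraints: tuple[tuple[int, str, float], ...]


_OPS = {
    ">": np.greater, ">=": np.greater_equal,
    "<": np.less, "<=": np.less_equal,
}


def pca_scores(matrix: ExpressionMatrix, genes: Sequence[str],
               n_components: int = 2) -> PcaScores:
    """PCA with genes as observations and samples as variables.

    Sample columns are centered (over the gene subset); component signs are
    fixed by forcing each component's largest-magnitude loading positive.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValidationError("need at least 3 genes for PCA")
    x = matrix.gene_rows(genes)
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(np.abs(xc) > 1e-12):
        raise ValidationError("no principal structure: all gene profiles identical")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    load = vt[:k]
    for j in range(k):  # deterministic sign
        lead = np.argmax(np.abs(load[j]))
        if load[j, lead] < 0:
            load[j] = -load[j]
            scores[:, j] = -scores[:, j]
    ev = np.square(s[:k]) / (len(genes) - 1)
    return PcaScores(genes=genes, scores=scores, loadings=load,
                     explained_variance=ev)


def pca_gene_subsets(matrix: ExpressionMatrix, genes: Sequence[str],
                     rules: Sequence[ScoreRule]) -> list[GeneSet]:
    """Apply explicit score-threshold rules to the PC1/PC2 gene scores."""
    pca = pca_scores(matrix, genes, n_components=2)
    out = []
    for rule in rules:
        keep = np.ones(len(pca.genes), dtype=bool)
        for comp, op, thr in rule.constraints:
            if comp not in (1, 2) or comp > pca.scores.shape[1]:
                raise ValidationError(f"rule {rule.name!r}: no component {comp}")
            keep &= _OPS[op](pca.scores[:, comp - 1], thr)
        out.append(GeneSet(
            name=rule.name,
            provenance=Provenance.SC,
            genes=tuple(g for g, k in zip(pca.genes, keep) if k),
            description="PCA score-rule subset",
            empty_allowed=True,
        ))
    return out
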