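"""Variance ranking, Ward clustering (vs a brute-force oracle), PCA subsets."""

import itertools

import numpy as np
import pytest

from confounderscan.cluster import (
    ScoreRule,
    extract_seeded_cluster,
    pca_gene_subsets,
    pca_scores,
    top_variable_genes,
    ward_cluster,
)
from confounderscan.core_io import ValidationError

from conftest import matrix_from


class TestTopVariableGenes:
    def test_rank_and_cut(self):
        m = matrix_from(["A", "B", "C"], ["s1", "s2", "s3", "s4"],
                        [[0, 2, 4, 6], [0, 1, 2, 3], [5, 5, 5, 5]])
        r = top_variable_genes(m, m.sample_ids, 2)
        assert r.top_genes == ("A", "B")
        assert r.rank_of("A") == 1 and r.rank_of("B") == 2

    def test_constant_gene_ranked_last(self):
        m = matrix_from(["A", "B"], ["s1", "s2", "s3"],
                        [[5, 5, 5], [0, 1, 2]])
        r = top_variable_genes(m, m.sample_ids, 1)
        assert r.sd_of("A") == 0.0
        assert r.gene_ids[-1] == "A"

    def test_sd_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 4))
        m = matrix_from(["g1", "g2", "g3"], ["a", "b", "c", "d"], vals)
        r = top_variable_genes(m, m.sample_ids, 3)
        for i, g in enumerate(m.gene_ids):
            mu = sum(vals[i]) / 4
            sd = (sum((v - mu) ** 2 for v in vals[i]) / 3) ** 0.5
            assert r.sd_of(g) == pytest.approx(sd, abs=1e-12)

    def test_tie_break_lexicographic(self):
        m = matrix_from(["Zed", "Abc"], ["s1", "s2"], [[0, 1], [0, 1]])
        r = top_variable_genes(m, m.sample_ids, 1)
        assert r.gene_ids == ["Abc", "Zed"]

    def test_errors(self):
        m = matrix_from(["A"], ["s1", "s2"], [[0, 1]])
        with pytest.raises(ValidationError):
            top_variable_genes(m, m.sample_ids, 2)
        with pytest.raises(ValidationError):
            top_variable_genes(m, ["s1"], 1)


def brute_force_ward(points):
    """Greedy Ward on raw points: recompute dSSE for every pair each step."""
    clusters = [[i] for i in range(len(points))]
    points = np.asarray(points, float)

    def sse(idx):
        x = points[idx]
        return float(((x - x.mean(axis=0)) ** 2).sum())

    merges, heights = [], []
    active = {i: [i] for i in range(len(points))}
    next_id = len(points)
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            d = sse(active[a] + active[b]) - sse(active[a]) - sse(active[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b))
        heights.append(d)
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return merges, heights


class TestWardCluster:
    def test_identical_pairs_merge_first_at_zero_height(self):
        m = matrix_from(["a", "b", "c", "d"], ["s1", "s2", "s3"],
                        [[0, 1, 2], [0, 1, 2], [9, 7, 5], [9, 7, 5]])
        d = ward_cluster(m, m.gene_ids, scale=False)
        assert d.heights[0] == pytest.approx(0.0, abs=1e-12)
        assert d.heights[1] == pytest.approx(0.0, abs=1e-12)
        order = d.leaf_order
        assert {order[0], order[1]} in ({"a", "b"}, {"c", "d"})

    def test_matches_brute_force_oracle_on_1d_profiles(self):
        pts = [0.0, 0.1, 10.0, 10.1]
        m = matrix_from(["g0", "g1", "g2", "g3"], ["s1"],
                        [[p] for p in pts])
        d = ward_cluster(m, m.gene_ids, scale=False)
        _, oracle_heights = brute_force_ward([[p] for p in pts])
        np.testing.assert_allclose(sorted(d.heights), sorted(oracle_heights),
                                   atol=1e-10)
        # first two merges pair the close points
        first_two = [set(map(int, mm)) for mm in d.merges[:2]]
        assert {0, 1} in first_two and {2, 3} in first_two

    def test_matches_brute_force_on_random_5_points(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 3))
        m = matrix_from([f"g{i}" for i in range(5)], ["a", "b", "c"], pts)
        d = ward_cluster(m, m.gene_ids, scale=False)
        _, oracle_heights = brute_force_ward(pts)
        np.testing.assert_allclose(np.sort(d.heights), np.sort(oracle_heights),
                                   rtol=1e-10)

    def test_two_point_closed_form(self):
        m = matrix_from(["a", "b"], ["s1", "s2"], [[0, 0], [3, 4]])
        d = ward_cluster(m, m.gene_ids, scale=False)
        assert d.heights[0] == pytest.approx(25.0 / 2.0)  # d^2 / 2

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(11)
        m = matrix_from([f"g{i}" for i in range(30)], [f"s{j}" for j in range(6)],
                        rng.normal(size=(30, 6)))
        d = ward_cluster(m, m.gene_ids)
        assert np.all(np.diff(d.heights) >= -1e-10)

    def test_missing_gene_rejected(self):
        m = matrix_from(["a", "b"], ["s1", "s2"], [[0, 1], [2, 3]])
        with pytest.raises(KeyError):
            ward_cluster(m, ["a", "nope"])


class TestSeededCluster:
    @staticmethod
    def _block_matrix():
        rng = np.random.default_rng(5)
        base = rng.normal(size=(1, 8))
        tight = base + 0.01 * rng.normal(size=(5, 8))       # 5 co-expressed genes
        rest = rng.normal(size=(95, 8)) * 3
        vals = np.vstack([tight, rest])
        return matrix_from([f"g{i}" for i in range(100)],
                           [f"s{j}" for j in range(8)], vals)

    def test_recovers_constructed_tight_cluster(self):
        m = self._block_matrix()
        d = ward_cluster(m, m.gene_ids, scale=False)
        gs = extract_seeded_cluster(d, ["g0", "g3"], max_size=20)
        assert set(gs.genes) == {"g0", "g1", "g2", "g3", "g4"}
        assert not gs.oversize

    def test_minimality_no_descendant_contains_all_seeds(self):
        m = self._block_matrix()
        d = ward_cluster(m, m.gene_ids, scale=False)
        gs = extract_seeded_cluster(d, ["g0", "g3"], max_size=20)
        node = next(n for n in range(d.n_leaves, 2 * d.n_leaves - 1)
                    if d.members(n) == gs.members)
        a, b = d.merges[node - d.n_leaves]
        for child in (a, b):
            assert not {"g0", "g3"} <= d.members(child)

    def test_single_seed_gives_first_merge(self):
        m = self._block_matrix()
        d = ward_cluster(m, m.gene_ids, scale=False)
        gs = extract_seeded_cluster(d, ["g0"], max_size=20)
        assert "g0" in gs.members and 2 <= len(gs) <= 20

    def test_forced_root_sets_oversize_flag(self):
        m = matrix_from(["a", "b", "c", "d"], ["s1", "s2"],
                        [[0, 0], [0.1, 0], [10, 10], [10.1, 10]])
        d = ward_cluster(m, m.gene_ids, scale=False)
        gs = extract_seeded_cluster(d, ["a", "c"], max_size=2)
        assert set(gs.genes) == {"a", "b", "c", "d"}
        assert gs.oversize

    def test_unknown_seed_named_in_error(self):
        m = matrix_from(["a", "b"], ["s1", "s2"], [[0, 1], [2, 3]])
        d = ward_cluster(m, m.gene_ids, scale=False)
        with pytest.raises(ValidationError, match="nope"):
            extract_seeded_cluster(d, ["nope"], max_size=2)


class TestPcaSubsets:
    @staticmethod
    def _two_block_matrix():
        rng = np.random.default_rng(9)
        s = 10
        up = np.tile(np.linspace(-2, 2, s), (50, 1)) + 0.05 * rng.normal(size=(50, s))
        down = -np.tile(np.linspace(-2, 2, s), (50, 1)) + 0.05 * rng.normal(size=(50, s))
        return matrix_from([f"g{i}" for i in range(100)],
                           [f"s{j}" for j in range(s)], np.vstack([up, down]))

    def test_pc1_sign_separates_blocks(self):
        m = self._two_block_matrix()
        pca = pca_scores(m, m.gene_ids)
        signs = np.sign(pca.scores[:, 0])
        assert len(set(signs[:50])) == 1 and len(set(signs[50:])) == 1
        assert signs[0] != signs[50]

    def test_symmetric_rule_splits_in_half(self):
        m = self._two_block_matrix()
        subsets = pca_gene_subsets(m, m.gene_ids, [
            ScoreRule("pos", ((1, ">", 0.0),)),
            ScoreRule("neg", ((1, "<", 0.0),)),
        ])
        assert len(subsets[0]) == 50 and len(subsets[1]) == 50
        assert subsets[0].members.isdisjoint(subsets[1].members)

    def test_explained_variance_matches_eigen_oracle(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=(20, 5))
        m = matrix_from([f"g{i}" for i in range(20)],
                        [f"s{j}" for j in range(5)], vals)
        pca = pca_scores(m, m.gene_ids)
        xc = vals - vals.mean(axis=0, keepdims=True)
        ev = np.linalg.eigvalsh(np.cov(xc, rowvar=False))[::-1]
        np.testing.assert_allclose(pca.explained_variance, ev[:2], rtol=1e-10)

    def test_sign_convention_deterministic(self):
        m = self._two_block_matrix()
        p1 = pca_scores(m, m.gene_ids)
        p2 = pca_scores(m, m.gene_ids)
        np.testing.assert_array_equal(p1.scores, p2.scores)
        lead = np.argmax(np.abs(p1.loadings[0]))
        assert p1.loadings[0, lead] > 0

    def test_degenerate_input_rejected(self):
        m = matrix_from(["a", "b", "c"], ["s1", "s2"],
                        [[1, 2], [1, 2], [1, 2]])
        with pytest.raises(ValidationError, match="principal"):
            pca_scores(m, m.gene_ids)
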