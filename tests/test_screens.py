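"""Biopsy relabeling and the four confounder selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confounderscan.cluster import top_variable_genes
from confounderscan.core_io import (
    Dose,
    GeneSet,
    Provenance,
    SampleRecord,
    SampleTable,
    Series,
    ValidationError,
)
from confounderscan.screens import (
    fc_screen,
    handling_stress_set,
    individual_effect_set,
    low_variance_tail,
    relabel_biopsy_order,
)

from conftest import make_table, matrix_from


class TestRelabelBiopsyOrder:
    def test_early_mapping(self, early_pair_table):
        rel = relabel_biopsy_order(early_pair_table)
        got = {r.recovery_time_h: r.biopsy_order for r in rel
               if r.individual_id == "m1"}
        assert got == {0: 1, 1: 2, 2: 3, 3: 4, 4: 5, 5: 6}

    def test_late_mapping_restarts_at_7p5(self):
        tbl = make_table([("m1", Series.LATE, (0, 7.5, 9, 10.5, 12),
                           Dose.NONE, False)])
        rel = relabel_biopsy_order(tbl)
        got = {r.recovery_time_h: r.biopsy_order for r in rel}
        assert got == {0: 1, 7.5: 1, 9: 2, 10.5: 3, 12: 4}

    def test_late_t0_dropped_with_alternative_switch(self):
        tbl = make_table([("m1", Series.LATE, (0, 7.5, 9, 10.5, 12),
                           Dose.NONE, False)])
        rel = relabel_biopsy_order(tbl, late_b1_includes_t0=False)
        assert len(rel) == 4
        assert all(r.recovery_time_h > 0 for r in rel)

    def test_off_grid_time_rejected(self):
        # domain enforcement happens at record construction already
        with pytest.raises(ValidationError):
            SampleRecord("x", "m1", Series.LATE, 6.0, Dose.NONE, False)


class TestFcScreen:
    @staticmethod
    def _matrix(ranges_by_gene, table):
        # gene value ramps linearly 0..range over each mouse's samples
        rows = []
        for rg in ranges_by_gene:
            row = []
            for ind, recs in table.by_individual().items():
                k = len(recs)
                row.extend(np.linspace(0, rg[ind], k))
            rows.append(row)
        sample_ids = [r.sample_id for recs in table.by_individual().values()
                      for r in recs]
        m = matrix_from([f"g{i}" for i in range(len(rows))], sample_ids, rows)
        return m

    def test_pass_requires_every_mouse(self, early_pair_table):
        tbl = early_pair_table
        m = self._matrix([{"m1": 1.2, "m2": 1.5},
                          {"m1": 1.2, "m2": 0.8},
                          {"m1": 0.0, "m2": 0.0}], tbl)
        res = fc_screen(m, tbl, 1.0)
        assert res.passing_genes == ("g0",)
        np.testing.assert_allclose(res.ranges[2], [0.0, 0.0], atol=1e-12)

    def test_single_sample_individual_rejected(self):
        tbl = make_table([("m1", Series.EARLY, (0,), Dose.NONE, False),
                          ("m2", Series.EARLY, (0, 1), Dose.NONE, False)])
        m = matrix_from(["g"], tbl.sample_ids, [[0, 1, 2]])
        with pytest.raises(ValidationError, match="m1"):
            fc_screen(m, tbl, 1.0)

    @given(st.floats(min_value=0.1, max_value=3.0),
           st.floats(min_value=0.0, max_value=2.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, thr, bump):
        tbl = make_table([("m1", Series.EARLY, (0, 1, 2), Dose.NONE, False),
                          ("m2", Series.EARLY, (0, 1, 2), Dose.NONE, False)])
        rng = np.random.default_rng(0)
        m = matrix_from([f"g{i}" for i in range(10)], tbl.sample_ids,
                        rng.normal(size=(10, 6)) * 1.5)
        lo = set(fc_screen(m, tbl, thr).passing_genes)
        hi = set(fc_screen(m, tbl, thr + bump).passing_genes)
        assert hi <= lo


def _ranking(sds):
    genes = list(sds)
    m = matrix_from(genes, ["s1", "s2"],
                    [[0.0, sd * np.sqrt(2)] for sd in sds.values()])
    return top_variable_genes(m, ["s1", "s2"], len(genes))


class TestLowVarianceTail:
    def test_lowest_k_selected(self):
        r = _ranking({"A": 0.1, "B": 0.2, "C": 0.9})
        gs = low_variance_tail(["A", "B", "C"], r, 2)
        assert set(gs.genes) == {"A", "B"}
        assert gs.provenance is Provenance.TD

    def test_k_equal_candidates_is_identity(self):
        r = _ranking({"A": 0.1, "B": 0.2, "C": 0.9})
        gs = low_variance_tail(["A", "C"], r, 2)
        assert set(gs.genes) == {"A", "C"}

    def test_union_of_tails_has_no_double_counting(self):
        r = _ranking({"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4})
        early = set(low_variance_tail(["A", "B", "C"], r, 2).genes)
        late = set(low_variance_tail(["B", "C", "D"], r, 2).genes)
        union = early | late
        assert union == {"A", "B", "C"}
        assert len(union) == len(early) + len(late) - len(early & late)

    def test_oversized_k_rejected(self):
        r = _ranking({"A": 0.1})
        with pytest.raises(ValidationError):
            low_variance_tail(["A"], r, 2)


class TestHandlingStressSet:
    def test_strict_threshold(self):
        r = _ranking({"A": 0.10, "B": 0.31, "C": 0.32, "D": 0.50})
        gs = handling_stress_set(["A", "B", "C", "D"], r, 0.32)
        assert set(gs.genes) == {"A", "B"}
        assert gs.provenance is Provenance.HS

    def test_zero_threshold_gives_empty(self):
        r = _ranking({"A": 0.1})
        gs = handling_stress_set(["A"], r, 1e-12)
        assert len(gs) == 0

    def test_all_below_is_identity(self):
        r = _ranking({"A": 0.1, "B": 0.2})
        gs = handling_stress_set(["A", "B"], r, 0.5)
        assert set(gs.genes) == {"A", "B"}


class TestIndividualEffectSet:
    def test_max_abs_rule_strict(self):
        coefs = {"g1": np.array([0.6, -0.1, 0.0]),
                 "g2": np.array([0.5, 0.5, -0.5]),
                 "g3": np.array([0.0, 0.0, 0.0])}
        gs = individual_effect_set(coefs, 0.5)
        assert set(gs.genes) == {"g1"}          # 0.5 fails the strict rule
        gs_incl = individual_effect_set(coefs, 0.5, inclusive=True)
        assert set(gs_incl.genes) == {"g1", "g2"}

    def test_exclusion_sets_remove_genes(self):
        coefs = {"g1": np.array([0.9]), "g2": np.array([0.9])}
        sc = GeneSet("SC-A", Provenance.SC, ("g2",))
        gs = individual_effect_set(coefs, 0.5, exclude=[sc])
        assert set(gs.genes) == {"g1"}

    def test_empty_fits_rejected(self):
        with pytest.raises(ValidationError):
            individual_effect_set({}, 0.5)
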