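import logging

import numpy as np
import pytest

from confounderscan.core_io import (
    Dose,
    ExpressionMatrix,
    SampleRecord,
    SampleTable,
    Series,
)

logging.disable(logging.WARNING)


def make_table(spec):
    """Build a SampleTable from (individual, series, times, dose, treated) tuples."""
    records = []
    for ind, series, times, dose, treated in spec:
        for t in times:
            records.append(SampleRecord(
                sample_id=f"{ind}_t{t:g}".replace(".", "p"),
                individual_id=ind,
                series=series,
                recovery_time_h=float(t),
                dose=dose,
                treated=treated,
            ))
    return SampleTable(records)


@pytest.fixture
def early_pair_table():
    """Two untreated early-series mice with the full 6-point grid."""
    return make_table([
        ("m1", Series.EARLY, (0, 1, 2, 3, 4, 5), Dose.NONE, False),
        ("m2", Series.EARLY, (0, 1, 2, 3, 4, 5), Dose.NONE, False),
    ])


@pytest.fixture
def wt_untreated_table():
    """Four untreated mice: two early, two late (shared WT-like grid)."""
    return make_table([
        ("m1", Series.EARLY, (0, 1, 2, 3, 4, 5), Dose.NONE, False),
        ("m2", Series.EARLY, (0, 1, 2, 3, 4, 5), Dose.NONE, False),
        ("m3", Series.LATE, (0, 7.5, 9, 10.5, 12), Dose.NONE, False),
        ("m4", Series.LATE, (0, 7.5, 9, 10.5, 12), Dose.NONE, False),
    ])


def matrix_from(genes, samples, values):
    return ExpressionMatrix(list(genes), list(samples), np.asarray(values, float))
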