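import numpy as np
import pandas as pd
import pytest

from lipodriver import cnv, exprstats, histone, simdata


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared across read-only tests."""
    return simdata.simulate_cohort(simdata.SimConfig(seed=11))


@pytest.fixture(scope="session")
def normed_default(default_cohort):
    cohort, _ = default_cohort
    matrix = exprstats.ExpressionMatrix(values=cohort.expression, groups=cohort.groups)
    normed, _ = exprstats.size_factor_normalize(matrix)
    return normed


@pytest.fixture(scope="session")
def catalog():
    return histone.GeneSetCatalog.default()


@pytest.fixture(scope="session")
def segments_default(default_cohort):
    """Copy-number segments for every tumor of the default cohort."""
    cohort, _ = default_cohort
    segments = {}
    for sample in cohort.config.tumor_samples:
        copies = cnv.coverage_to_copy(cohort.tumor_depth[sample],
                                      cohort.normal_depth[sample])
        segments[sample] = cnv.segment_copy_number(copies)
    return segments


def overlap_truth(calls: pd.DataFrame, events: pd.DataFrame) -> tuple[int, int, int]:
    """(true positives, false negatives, false positives) by interval overlap."""
    tp = fn = fp = 0
    for ev in events.itertuples():
        hit = calls[(calls["chrom"] == ev.chrom) & (calls["start"] < ev.end)
                    & (calls["end"] > ev.start)]
        if hit.empty:
            fn += 1
        else:
            tp += 1
    for c in calls.itertuples():
        hit = events[(events["chrom"] == c.chrom) & (events["start"] < c.end)
                     & (events["end"] > c.start)]
        if hit.empty:
            fp += 1
    return tp, fn, fp
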