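import numpy as np
import pandas as pd
import pytest

from myomics import synthetic


@pytest.fixture(scope="session")
def cfg():
    return synthetic.SimConfig(seed=1)


@pytest.fixture(scope="session")
def expression_data(cfg):
    """(expr, deg_table, csa, labels) for the default study conditions."""
    return synthetic.make_expression(cfg)


@pytest.fixture(scope="session")
def methylome_data(cfg):
    """(tracks, planted segment table, planted DMR table)."""
    return synthetic.make_methylome(cfg)


@pytest.fixture(scope="session")
def peak_data(cfg):
    """(replicate peak sets, count matrix, core peaks, planted DAR table)."""
    return synthetic.make_peaks(cfg)


@pytest.fixture(scope="session")
def tf_resources(cfg):
    return synthetic.make_tf_resources(cfg)


@pytest.fixture(scope="session")
def fiber_mosaic(cfg):
    """(rgb, label mask, truth table) for one WGA-style mosaic."""
    return synthetic.make_fiber_image(cfg)


def interval_jaccard(truth_intervals, recovered_intervals) -> float:
    """bp-level Jaccard between two interval sets (same chromosome)."""
    inter = sum(max(0, min(a[1], b[1]) - max(a[0], b[0]))
                for a in truth_intervals for b in recovered_intervals)
    total = (sum(e - s for s, e in truth_intervals)
             + sum(e - s for s, e in recovered_intervals) - inter)
    return inter / total if total else float("nan")
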