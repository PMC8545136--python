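"""Shared fixtures: expensive synthetic fields are generated once per session."""

import warnings

import numpy as np
import pytest

from tolfish import logic, pipeline, simulate

WT_MXYL = logic.Condition(logic.Genotype.WT_PWW0, logic.Inducer.M_XYLENE)


def analyze_fields(fields, cfg=None):
    """Run the default analysis on (stack, truth) pairs using the truth masks."""
    cfg = cfg or pipeline.DEFAULT_CONFIG["analyze"]
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (stack, truth) in enumerate(fields):
            results.append(pipeline.analyze_field(stack, cfg, i, truth.labels))
    return results


def match_foci(truth_df, det_df, max_dist=1.0):
    """One-to-one optimal matching of truth vs detected foci of one channel.

    Returns (matches, n_missed, n_spurious) where matches is a list of
    (truth_row_index, det_row_index, distance).
    """
    from scipy.optimize import linear_sum_assignment

    if len(truth_df) == 0 or len(det_df) == 0:
        return [], len(truth_df), len(det_df)
    d = np.hypot(
        truth_df.x.values[:, None] - det_df.x.values[None, :],
        truth_df.y.values[:, None] - det_df.y.values[None, :],
    )
    ri, ci = linear_sum_assignment(d)
    matches = [(i, j, d[i, j]) for i, j in zip(ri, ci) if d[i, j] <= max_dist]
    return matches, len(truth_df) - len(matches), len(det_df) - len(matches)


@pytest.fixture(scope="session")
def default_run():
    """Default WT + m-xylene preset, 8 fields x 30 cells, analyzed end to end."""
    params = simulate.SimParams(n_cells=30)
    fields = simulate.generate_fields(params, WT_MXYL, 11, 8)
    return {
        "params": params,
        "fields": fields,
        "results": analyze_fields(fields),
    }


@pytest.fixture(scope="session")
def single_field():
    """One default field with its analysis, for cheap per-cell tests."""
    params = simulate.SimParams(n_cells=20)
    fields = simulate.generate_fields(params, WT_MXYL, 5, 1)
    return {
        "params": params,
        "stack": fields[0][0],
        "truth": fields[0][1],
        "result": analyze_fields(fields)[0],
    }
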