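import logging

import numpy as np
import pytest

import riskaim as ra
import riskaim.optimality as op
import riskaim.preprocess as pp

logging.getLogger("riskaim").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def timing_schemes():
    return ra.default_schemes("timing")


@pytest.fixture(scope="session")
def distance_schemes():
    return ra.default_schemes("distance")


def grid_search_optimal_aim(sigma, scheme, resolution=0.1, hi_pad=3.0):
    """Independent exhaustive-search oracle for the optimal aim point."""
    grid = np.arange(scheme.lower, scheme.upper + hi_pad * sigma + resolution, resolution)
    from riskaim.payoff import _expected_gain_vec

    eg = _expected_gain_vec(grid, sigma, scheme)
    return float(grid[np.argmax(eg)]), float(eg.max())


def light_pipeline(trials):
    """Filter + summarize + optimality without the bootstrap stage."""
    filtered = ra.filter_trials(trials)
    results = []
    for (_, _), grp in filtered.groupby(["participant", "modality"], sort=True):
        results.extend(op.participant_optimality(pp.summarize_blocks(grp)))
    return op.results_to_frame(results), filtered
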