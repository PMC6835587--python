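import numpy as np
import pandas as pd
import pytest

import dims_stability as ds


@pytest.fixture(scope="session")
def tiny_library() -> ds.MetaboliteLibrary:
    return ds.generate_library(8, (70.0, 600.0), 2, seed=3)


@pytest.fixture(scope="session")
def one_condition_design() -> ds.StudyDesign:
    """3 pools, reference + one freeze/thaw condition, triplicates."""
    return ds.generate_design(3, {"freeze_thaw": [7]}, 3)


@pytest.fixture(scope="session")
def small_design() -> ds.StudyDesign:
    return ds.generate_design(3, {"freeze_thaw": [1, 4, 7], "room": [8, 168]}, 3)


def annotate_study(library, design, effects):
    """Generator -> matching -> summation chain used by many tests."""
    peaks = ds.simulate_peak_tables(library, design, effects)
    matches = ds.match_peaks(peaks, library)
    return ds.summed_intensities(matches, library, design)


@pytest.fixture(scope="session")
def noise_free_matrix(tiny_library, small_design):
    return annotate_study(tiny_library, small_design, ds.EffectSpec(seed=0))
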