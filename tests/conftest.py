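import numpy as np
import pandas as pd
import pytest

from meiopattern import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def germline_movie():
    """Small movie with a mid→late-pachytene transition (session-cached)."""
    cfg = sd.GermlineConfig(n_rows=30, nuclei_per_row=7, seed=0)
    kin = sd.FocusKineticsConfig(seed=0)
    tracks, detections, truth = sd.gen_germline_movie(cfg, kin, n_frames=40, rng=10)
    return cfg, kin, tracks, detections, truth


@pytest.fixture(scope="session")
def stable_trace_set():
    """Six SC traces carrying exactly one stable focus each, 40 frames."""
    kin = sd.FocusKineticsConfig(
        persistent_per_chromosome=1,
        blinking_rate_on=0.0,
        blinking_rate_off=0.0,
        n_blinking_sites_per_chromosome=0,
    )
    traces, placements = sd.gen_sc_traces(kin, n_nuclei=1, rng=7)
    detections = sd.gen_trace_movie_detections(traces, placements, kin, n_frames=40, rng=8)
    return kin, traces, placements, detections
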