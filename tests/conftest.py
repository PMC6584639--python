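import numpy as np
import pytest

from kifquant import synthgen as sg


@pytest.fixture(scope="session")
def wild_type_roundtrip():
    """Simulate -> render -> trace -> summarize at the wild-type regime.

    Uses 60 microtubules: the censored-exponential run-length estimate has
    a ~12% sampling SD per 30 microtubules, so the larger panel keeps the
    recovery comparison meaningfully tighter than its tolerance. Shared
    across tests because tracing kymographs is the most expensive step in
    the suite. ``min_duration_s`` matches the tracer's 10-frame minimum
    track length at 0.1 s/frame.
    """
    from kifquant import motility as mo

    observations = []
    n_true_events = 0
    for m in range(60):
        tracks, events = sg.sim_motility(15.0, 3.0, sg.WILD_TYPE_MOTILITY, seed=1000 + m)
        n_true_events += len(events)
        kymo = sg.render_kymograph(tracks, 15.0, 180.0, seed=50_000 + m)
        runs = mo.trace_kymograph(kymo)
        observations.append(mo.MTObservation(15.0, 3.0, runs))
    summary = mo.summarize(observations, min_duration_s=1.0)
    return summary, n_true_events


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
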