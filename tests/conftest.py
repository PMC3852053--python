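import numpy as np
import pandas as pd
import pytest

from csfarray import SimulationConfig, simulate_expression_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated profiling run shared across tests (read-only)."""
    cfg = SimulationConfig(n_transcripts=400, seed=11)
    return simulate_expression_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_probe_stats(rows):
    """Probe-stat frame from (probe_id, transcript_id, signed_fold, p_bh) tuples."""
    return pd.DataFrame(rows, columns=["probe_id", "transcript_id", "signed_fold", "p_bh"])
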