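import numpy as np
import pytest

from crpdt.engine import run_scenario, scenario_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario_runs():
    """One 10^5-primary run per scenario at a common seed (shared: ~10 s)."""
    out = {}
    for sid in ("water_only", "ps_only", "tb_ps", "tb_only", "gd_ps"):
        tally, manifest = run_scenario(scenario_config(sid, primaries=100_000, seed=7))
        out[sid] = (tally, manifest)
    return out
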