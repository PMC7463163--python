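import numpy as np
import pandas as pd
import pytest

import hippoconn as h


@pytest.fixture(scope="session")
def toy_atlas() -> h.TargetAtlas:
    """5-target atlas: 3 DMN + 2 VIS."""
    table = pd.DataFrame({
        "roi_id": [1, 2, 3, 4, 5],
        "x": [0.0, 10.0, -10.0, 5.0, -5.0],
        "y": [0.0, 20.0, -20.0, 15.0, -15.0],
        "z": [0.0, 5.0, -5.0, 10.0, -10.0],
        "network": ["DMN", "DMN", "DMN", "VIS", "VIS"],
    })
    return h.TargetAtlas(table=table)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick two-network cohort with a planted right_body-DMN group effect."""
    cfg = h.CohortConfig(
        n_minus=10, n_plus=12, n_targets=30,
        partition_spec={"DMN": 18, "VIS": 12},
        n_timepoints=120, rng_seed=11, base_coupling=0.3,
        effect_map={("right_body", "DMN"): h.Effect(group_delta=0.28)},
    )
    phen, ts, vols, atlas = h.simulate_cohort(cfg)
    fcs = [h.fc_matrix(h.bandpass(t), atlas) for t in ts]
    return cfg, phen, ts, vols, atlas, fcs


@pytest.fixture(scope="session")
def null_cohort():
    """Same shape, no planted effect."""
    cfg = h.CohortConfig(
        n_minus=10, n_plus=12, n_targets=30,
        partition_spec={"DMN": 18, "VIS": 12},
        n_timepoints=120, rng_seed=5,
    )
    phen, ts, vols, atlas = h.simulate_cohort(cfg)
    fcs = [h.fc_matrix(h.bandpass(t), atlas) for t in ts]
    return cfg, phen, ts, vols, atlas, fcs
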