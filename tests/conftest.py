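import numpy as np
import pandas as pd
import pytest

from ecoevo.synthetic import (
    CommunityConfig,
    evolved_configs,
    make_default_community,
)


@pytest.fixture(scope="session")
def community():
    return make_default_community(4, 10, seed=7)


@pytest.fixture(scope="session")
def treatment_configs(community):
    return evolved_configs(community, effect_size=1.0, seed=7)


@pytest.fixture()
def tiny_config():
    """A hand-specified 2-species, 4-compound community (exact truth)."""
    return CommunityConfig(
        species_ids=["A", "B"],
        compound_ids=["glucose", "choline", "acetate", "lactate"],
        base_medium=np.array([1.0, 2.0, 0.0, 0.0]),
        r=np.array([2.0, 1.5]),
        K=np.array([1e9, 1e9]),
        U=np.array([[0.5, 0.25, 0.0, 0.0], [0.5, 0.0, 0.0, 0.0]]),
        P=np.array([[0.0, 0.0, 0.8, 0.0], [0.0, 0.0, 0.0, 0.6]]),
        noise_od=0.0,
        noise_peak=0.0,
    )


@pytest.fixture()
def small_peak_table():
    rows = []
    values = {
        "s1": {"p1": 1.0, "p2": 2.0, "p3": 0.5},
        "s2": {"p1": 0.5, "p2": 1.0, "p3": 0.2},
    }
    for sid, peaks in values.items():
        for pk, v in peaks.items():
            rows.append(
                {"sample_id": sid, "peak_id": pk, "integral": v,
                 "species": "A", "treatment": "ancestral",
                 "substrate": "unused", "replicate": 1}
            )
    return pd.DataFrame.from_records(rows)
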