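import numpy as np
import pandas as pd
import pytest

from blockcpm import SimulationConfig, simulate_study, subject_average_edges, stage_rng


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 40-parcel, 30-per-group study: fast, but all stages have signal."""
    return SimulationConfig(
        p=40, n_per_group=30, n_sites=3,
        mask_sizes={"sa_pos": 60, "sa_neg": 40, "wm_pos": 70, "wm_neg": 50},
        overlap_spec={}, n_common=30, n_differential=30, n_regions=5)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def small_edges(small_config, small_study):
    """Subject × E task-average edge vectors plus aligned behavior/groups."""
    ds = small_study
    edges = subject_average_edges(ds.subjects, ds.behavior, ds.ground_truth,
                                  small_config, seed=stage_rng(11, 3))
    subj = pd.DataFrame([vars(s) for s in ds.subjects])
    acc0 = (ds.behavior[ds.behavior["condition"] == "zero_back"]
            .groupby("subject_id")["accuracy"].mean())
    return {
        "edges": edges,
        "behavior": acc0.loc[subj["subject_id"]].to_numpy(),
        "groups": subj["group"].to_numpy(),
        "sites": subj["site_id"].to_numpy(),
        "a_sa": subj["a_sa"].to_numpy(),
        "dataset": ds,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
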