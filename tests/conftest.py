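import numpy as np
import pandas as pd
import pytest

from evoloss import synthetic_data as sd


@pytest.fixture(scope="session")
def experiment():
    """Default-size simulated experiment shared by read-only tests."""
    return sd.simulate_experiment(seed=11, include_curves=True, include_screen=False)


@pytest.fixture(scope="session")
def surviving(experiment):
    return experiment.lineages[experiment.lineages["survived"]]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_design_frame(lineages: pd.DataFrame):
    """Evolved-rate observations grouped per genotype, WT separated."""
    surv = lineages[lineages["survived"]]
    wt = surv.loc[surv["module"] == "wild_type", "evolved_rate"].to_numpy()
    strains = {
        str(g): grp["evolved_rate"].to_numpy()
        for g, grp in surv[surv["module"] != "wild_type"].groupby("genotype_id")
    }
    return strains, wt
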