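import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cyclequant.datatypes import AbundanceMatrix, ChannelDesign
from cyclequant.tmt_sim import SimConfig, simulate_experiment


def make_design(n_plexes=2, conditions=("AP", "Ec", "T1h", "T4h"),
                n_refs=1) -> ChannelDesign:
    """Small study design: one channel per condition per plex plus GS refs."""
    rows = []
    for p in range(n_plexes):
        plex = f"P{p+1}"
        for cond in conditions:
            rows.append((plex, cond, cond, p + 1, False))
        for j in range(n_refs):
            rows.append((plex, f"GS{j+1}", "GS", p + 1, True))
    return ChannelDesign(pd.DataFrame(
        rows, columns=["plex_id", "channel_label", "condition", "replicate",
                       "is_reference"],
    ))


def make_matrix(design: ChannelDesign, n_proteins=6, seed=0,
                stage="raw") -> AbundanceMatrix:
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.lognormal(8, 1, (n_proteins, len(design.channel_ids))),
        index=pd.Index([f"Bd{i:03d}" for i in range(n_proteins)],
                       name="protein_id"),
        columns=design.channel_ids,
    )
    return AbundanceMatrix(data, stage)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across tests."""
    return simulate_experiment(
        SimConfig(n_predator_proteins=400, n_prey_proteins=150, seed=11)
    )


@pytest.fixture(scope="session")
def small_result(small_study):
    from cyclequant import pipeline

    return pipeline.run_on_study(small_study)
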