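"""Shared fixtures: one default synthetic pipeline run reused across tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ossubtype as ost

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

SEED = 1


@pytest.fixture(scope="session")
def default_config():
    return ost.SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def sc_data(default_config):
    return ost.simulate_single_cell(default_config)


@pytest.fixture(scope="session")
def norm_adata(sc_data):
    adata, _ = sc_data
    return ost.lognormalize(ost.filter_cells_genes(adata))


@pytest.fixture(scope="session")
def marker_stats(norm_adata):
    labels = norm_adata.obs["true_cluster"].to_numpy()
    return {
        grp: ost.wilcoxon_one_vs_rest(norm_adata, labels, cluster)
        for grp, cluster in ost.GROUP_TERMINAL_CLUSTER.items()
    }


@pytest.fixture(scope="session")
def panel(marker_stats):
    return ost.select_specific_panel(marker_stats)


@pytest.fixture(scope="session")
def bulk_cohort(default_config):
    return ost.simulate_bulk_cohort(default_config)


@pytest.fixture(scope="session")
def consensus_result(bulk_cohort, panel):
    expr, _, _ = bulk_cohort
    model = ost.ConsensusSubtyper(expr, panel, n_resamples=100)
    return model.fit(seed=SEED)


@pytest.fixture(scope="session")
def ihc_panel():
    return ost.MarkerPanel(
        {"A": ["ALKBH5", "TOM1L2"], "B": ["CDK4", "LMO7"], "C": ["COL6A3", "THBS2"]}
    )


def truth_series(truth) -> pd.Series:
    return pd.Series(truth.bulk_group)


def group_accuracy(assigned: pd.Series, truth) -> float:
    ts = truth_series(truth)
    return float((assigned == ts.loc[assigned.index]).mean())
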