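"""Shared fixtures: small synthetic cohorts and cached heavy experiments.

Heavy recovery experiments (CNV cohort scoring, GNN trainings) are
session-scoped so the acceptance tests and the property tests share one
computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

import spotgin as sg
from spotgin import experiments as ex

SEED = 2026


@pytest.fixture(scope="session")
def small_cohort():
    """Two tiny sections for unit tests (marginal mode, no CNV events)."""
    return sg.generate_cohort(n_samples=2, grid=(12, 12), n_genes=250,
                              n_classes=2, seed=SEED,
                              subclass_mode="marginal", events=None)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return small_cohort.datasets[0]


@pytest.fixture(scope="session")
def small_nm(small_dataset):
    nm = sg.normalize_dataset(small_dataset)
    sg.select_hvg_joint([nm], 40)
    return nm


@pytest.fixture(scope="session")
def texture_bundles():
    return ex.gnn_bundles(SEED, "texture")


@pytest.fixture(scope="session")
def marginal_bundles():
    return ex.gnn_bundles(SEED, "marginal")


@pytest.fixture(scope="session")
def texture_ablation_runs(texture_bundles):
    """k=0 vs k=3 on the neighborhood-texture task, five training seeds."""
    rows = []
    for seed in range(SEED, SEED + 5):
        table = ex.texture_ablation(seed, bundles=texture_bundles)
        rows.append({"seed": seed,
                     "k0": float(table.loc[0, "accuracy"]),
                     "k3": float(table.loc[3, "accuracy"])})
    return rows


@pytest.fixture(scope="session")
def control_ablation_run(marginal_bundles):
    table = ex.control_ablation(SEED, bundles=marginal_bundles)
    return {"k0": float(table.loc[0, "accuracy"]),
            "k3": float(table.loc[3, "accuracy"])}


@pytest.fixture(scope="session")
def multitask_run(marginal_bundles):
    return ex.multitask(SEED, bundles=marginal_bundles)


@pytest.fixture(scope="session")
def cnv_recovery_run():
    return ex.cnv_recovery(SEED)


@pytest.fixture(scope="session")
def ihc_recovery_run():
    return ex.ihc_recovery(SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
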