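import numpy as np
import pytest

from spimpute import (
    SimulationConfig,
    simulate_paired,
    select_anchor_genes,
)
from spimpute.anchors import AnchorReport
from spimpute.impute import split_genes
from spimpute.model import ModelConfig, SpatialImputationModel


SMALL_SIM = dict(n_sc=400, n_sp=300, n_genes=100, panel_size=60, seed=0)


@pytest.fixture(scope="session")
def small_paired():
    """A small paired dataset with ground truth, shared across tests."""
    return simulate_paired(SimulationConfig(**SMALL_SIM))


def _truth_rates(paired, truth, genes):
    """Generative NB mean rates of `genes` for the spatial cells."""
    full_idx = {g: i for i, g in enumerate(paired.sc.gene_names)}
    sp_rho = truth.rho[truth.n_sc:]
    return np.stack(
        [truth.spatial_library * sp_rho[:, full_idx[g]] for g in genes],
        axis=1)


@pytest.fixture(scope="session")
def trained_small(small_paired):
    """A trained model on the small dataset with a 70/30 panel-gene split.

    Returns a dict with the results object, the datasets, the train/test
    gene lists, and the ground-truth rates for the test genes.
    """
    paired, truth = small_paired
    report = select_anchor_genes(paired)
    train, test = split_genes(list(report.kept_genes), seed=0)
    sub = report.table.loc[train].copy()
    sub["kept"] = True
    train_report = AnchorReport(table=sub, r_min=0.5, p_max=0.05)
    config = ModelConfig(epochs=60, seed=0)
    results = SpatialImputationModel(
        paired, anchors=train_report, config=config).fit()
    return {
        "paired": paired,
        "truth": truth,
        "results": results,
        "train_genes": train,
        "test_genes": test,
        "test_truth": _truth_rates(paired, truth, test),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
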