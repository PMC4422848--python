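import numpy as np
import pytest

import pubertwin as pt
from pubertwin.model import FamilyData


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def make_pair_data(
    truth, n_mz, n_dz, seed, dropout=0.0, n_singletons=0
) -> FamilyData:
    """Simulate pair phenotype arrays straight from the factor model."""
    rng = np.random.default_rng(seed)
    p = truth.n_phenotypes
    blocks, zygs = [], []
    if n_mz:
        blocks.append(pt.draw_pair_phenotypes(truth, "MZ", n_mz, rng))
        zygs += ["MZ"] * n_mz
    if n_dz:
        blocks.append(pt.draw_pair_phenotypes(truth, "DZ", n_dz, rng))
        zygs += ["DZ"] * n_dz
    y = np.vstack(blocks)
    if dropout and p == 4:
        drop = rng.random((len(y), 2)) < dropout
        for t in range(2):
            y[drop[:, t], p * t + 2] = np.nan
            y[drop[:, t], p * t + 3] = np.nan
    if n_singletons:
        extra = pt.draw_pair_phenotypes(truth, "DZ", n_singletons, rng)
        extra[:, p:] = np.nan
        y = np.vstack([y, extra])
        zygs += ["DZ"] * n_singletons
    return FamilyData(y, np.array(zygs))


@pytest.fixture(scope="session")
def fsh_truth():
    """FSH-like longitudinal ground truth with a planted pure-E change coupling."""
    return pt.plant_coupling(pt.default_path_model(), "e", 0.5)


@pytest.fixture(scope="session")
def null_truth():
    """Same structure but no hormone-density coupling anywhere."""
    return pt.default_path_model()


@pytest.fixture(scope="session")
def fitted_coupled(fsh_truth):
    """A converged full fit on a medium simulated cohort (shared across tests)."""
    data = make_pair_data(fsh_truth, 300, 300, seed=11, dropout=0.3)
    model = pt.TwinACEModel(data)
    res = model.fit(n_starts=2, seed=0)
    return model, res


@pytest.fixture(scope="session")
def small_cohort(fsh_truth, null_truth):
    """Small full synthetic cohort with voxel maps and a planted cluster."""
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1:3, 1:3, 1:3] = True
    cfg = pt.SimulationConfig(
        rng_seed=7,
        n_mz_pairs=40,
        n_dz_pairs=40,
        n_singletons=5,
        path_model=null_truth,
        cluster_model=fsh_truth,
        grid_shape=(4, 4, 4),
        signal_cluster=mask,
        dropout_rate_occasion2=0.3,
    )
    return pt.simulate_cohort(cfg)
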