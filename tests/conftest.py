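import numpy as np
import pytest

import varitx


@pytest.fixture(scope="session")
def default_cohort():
    """Desk-scale cohort at the generator defaults (20 x 4 x 300)."""
    return varitx.simulate_cohort(varitx.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_variability(default_cohort):
    return varitx.VariabilityModel(default_cohort.stack).fit()


@pytest.fixture(scope="session")
def planted_expression():
    """500 voxels x 1000 genes with 20 signal genes at effect 0.8."""
    rng = np.random.default_rng(11)
    coords = rng.uniform(0.0, 60.0, size=(500, 3))
    gradient = (coords[:, 0] - coords[:, 0].min()) / np.ptp(coords[:, 0])
    expr, signal = varitx.simulate_expression(
        gradient, varitx.ExpressionConfig(n_genes=1000, n_signal_genes=20,
                                          effect=0.8, seed=12))
    y = gradient + 0.1 * rng.standard_normal(500)
    return {"coords": coords, "gradient": gradient, "expr": expr,
            "signal": signal, "y": y}


@pytest.fixture(scope="session")
def planted_pls(planted_expression):
    model = varitx.PLSModel(planted_expression["expr"],
                            planted_expression["y"])
    return model.fit(n_boot=500, seed=13)


@pytest.fixture(scope="session")
def smooth_map_100():
    """A 100-voxel spatially smooth map with its weight matrix and basis."""
    rng = np.random.default_rng(3)
    coords = rng.uniform(0.0, 60.0, size=(100, 3))
    x = (np.sin(coords[:, 0] / 10.0) + 0.5 * coords[:, 1] / 60.0
         + 0.1 * rng.standard_normal(100))
    w = varitx.build_weight_matrix(coords, k=8)
    basis = varitx.moran_eigenbasis(w)
    return {"coords": coords, "map": x, "weights": w, "basis": basis}
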