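import numpy as np
import pytest

from formuopt.design import FactorSpec, generate_ccd
from formuopt.oracle import ccd_fixture_responses, load_fixture


@pytest.fixture(scope="session")
def study_factors():
    return [
        FactorSpec("X1", center=1.0, half_range=0.5),
        FactorSpec("X2", center=0.1, half_range=0.1),
        FactorSpec("X3", center=1.0, half_range=0.5),
    ]


@pytest.fixture(scope="session")
def ccd_design(study_factors):
    return generate_ccd(study_factors, alpha=1.633, n_center_cube=4, n_center_axial=2)


@pytest.fixture(scope="session")
def ccd_with_responses():
    return ccd_fixture_responses()


@pytest.fixture(scope="session")
def table2_init():
    init = load_fixture("table2_init")
    X = init[["X1", "X2", "X3"]].to_numpy(float)
    y = init["Y2"].to_numpy(float)
    return X, y


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230363)


@pytest.fixture(scope="session")
def eq4_grid_optimum():
    """Brute-force 201^3 grid maximum of the Y2 surface over the scan box."""
    from formuopt.oracle import BO_BOUNDS, EQ4_Y2

    density = 201
    x2 = np.linspace(*BO_BOUNDS[1], density)
    x3 = np.linspace(*BO_BOUNDS[2], density)
    G2, G3 = np.meshgrid(x2, x3, indexing="ij")
    best, best_x = -np.inf, None
    for x1 in np.linspace(*BO_BOUNDS[0], density):
        pts = np.column_stack([np.full(G2.size, x1), G2.ravel(), G3.ravel()])
        vals = EQ4_Y2.predict(pts)
        i = int(np.argmax(vals))
        if vals[i] > best:
            best, best_x = float(vals[i]), pts[i]
    return best_x, best
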