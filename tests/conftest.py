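import numpy as np
import pytest

import bmabench as bb


@pytest.fixture(scope="session")
def father_son():
    """Three (father, son) height pairs reported to the nearest inch; the
    standardized regression of son on father has R^2 = 1 exactly."""
    X = np.array([[62.5], [67.5], [70.5]])
    y = np.array([64.5, 69.5, 72.5])
    return bb.standardize(X, y)


@pytest.fixture(scope="session")
def small_signal_data():
    """n=200, p=8 AR(0.5) design with 3 strong planted signals."""
    spec = bb.SyntheticSpec(n=200, p=8, correlation_model=("ar", 0.5),
                            true_support_size=3, effect_scale=1.0,
                            target_r2=0.8, seed=11)
    design = bb.generate_design(spec)
    truth = bb.make_true_model(spec, design)
    y = bb.parametric_bootstrap(truth, design.X, 1, seed=12)[0]
    data = bb.RegressionData(design.X, y - y.mean())
    return data, truth
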