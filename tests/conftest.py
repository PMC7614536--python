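import numpy as np
import pytest

from vitdmet.kinetic_model import FullParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_full_params(rng, *, no_enzyme_dynamics=False):
    """Log-uniform positive full-model parameter draw for property sweeps."""

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return FullParams(
        P25=lu(0.5, 20.0),
        a=lu(0.05, 5.0),
        K=lu(5.0, 100.0),
        k3=lu(1e-3, 2.0),
        V4=lu(1e-4, 0.5),
        k5=lu(1e-3, 2.0),
        k6=lu(1e-2, 2.0),
        V7=lu(1e-4, 0.5),
        k8=lu(1e-2, 2.0),
        k9=lu(1e-2, 2.0),
        k10=lu(1e-2, 2.0),
        k11=lu(1e-2, 2.0),
        k12=0.0 if no_enzyme_dynamics else lu(1e-3, 1.0),
        p24=0.0 if no_enzyme_dynamics else lu(1e-2, 5.0),
        k14=0.0 if no_enzyme_dynamics else lu(1e-2, 2.0),
    )
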