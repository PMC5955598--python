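import numpy as np
import pytest

import filaturing as ft


@pytest.fixture(scope="session")
def chain40():
    return ft.build_chain(40)


@pytest.fixture(scope="session")
def params_unstable():
    """Inside the deterministic Turing region (D_S/D_N = 3, β_S = 3.7)."""
    return ft.synthetic.preset("fig3_red")


@pytest.fixture(scope="session")
def params_stable():
    """Just outside the region (β_S = 3.65): homogeneous state stable."""
    return ft.synthetic.preset("fig3_blue")


@pytest.fixture(scope="session")
def eq_unstable(params_unstable):
    return ft.reference_equilibrium(params_unstable)


@pytest.fixture(scope="session")
def eq_stable(params_stable):
    return ft.reference_equilibrium(params_stable)


@pytest.fixture(scope="session")
def decoupled_params():
    """No feedback, no complex degradation: three independent linear species."""
    return ft.ModelParams(
        alpha_R=0.2, alpha_S=0.1, alpha_N=0.3, beta_R=0.0, beta_S=0.0,
        k_R=0.2, k_S=0.1, k_N=0.7, mu_S=0.0, mu_N=0.0, D_S=3.0, D_N=1.0,
    )


def equilibrium_counts(eq, volume, n_cells):
    """Uniform integer initial counts at the rounded equilibrium."""
    return np.tile(np.rint(eq.state * volume).astype(np.int64), (n_cells, 1))
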