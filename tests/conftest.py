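import numpy as np
import pytest

import poroindent as pi


@pytest.fixture(scope="session")
def afm_params():
    """Soft agarose-like material as characterized by micro-indentation."""
    return pi.MaterialParams(E=28e3, nu=0.12, D=4.5e-10)


@pytest.fixture(scope="session")
def macro_params():
    """Agarose-like material as characterized by macro-indentation."""
    return pi.MaterialParams(E=21.25e3, nu=0.24, D=5e-8)


@pytest.fixture(scope="session")
def paam_params():
    """Polyacrylamide-like material: high Poisson ratio, slow drainage."""
    return pi.MaterialParams(E=11.24e3, nu=0.425, D=6.43e-9)


@pytest.fixture(scope="session")
def geometry75():
    return pi.Geometry(R=7.5e-3)


@pytest.fixture(scope="session")
def afm_suite_noiseless(afm_params):
    """The 24-observation force-clamp micro-indentation suite, no noise."""
    proto = pi.emulate_paper_protocols("afm_agarose06")
    return pi.simulate_ramp_suite(afm_params, proto)


@pytest.fixture(scope="session")
def surrogate_curve(macro_params, geometry75):
    """One mid-regime ramp-and-hold surrogate curve (tau_R ~ 0.22)."""
    return pi.simulate_relaxation_curve(
        macro_params, geometry75, delta_M=3e-3, t_R=100.0,
        n_ramp=200, n_hold=800,
    )
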