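import numpy as np
import pytest

import surftherm as st


@pytest.fixture(scope="session")
def thermo():
    return st.ThermoState(300.0)


@pytest.fixture(scope="session")
def system():
    return st.SurfactantSystem(volume_v=0.76, delta_s=0.5, b2_3d=-0.1)


@pytest.fixture(scope="session")
def micelle_model():
    """Study-condition double-exponential micelle free-energy model."""
    return st.MicelleFreeEnergyModel(dg_inf=-38.0, amp_a=0.5, alpha1=0.48,
                                     alpha2=0.026)


@pytest.fixture(scope="session")
def eos_truth(thermo):
    """Ground-truth synthetic equation of state (study-condition defaults)."""
    from surftherm.synth import DEFAULT_EOS_COEFFS

    return st.EquationOfState(
        coefficients=np.asarray(DEFAULT_EOS_COEFFS),
        thermal_energy=thermo.kt,
        gamma_max=1.6,
    )


@pytest.fixture(scope="session")
def adsorption_curve(eos_truth):
    """Pi-integration curve anchored at the study's zero-coverage value."""
    return st.pi_integrate(eos_truth, -63.5)
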