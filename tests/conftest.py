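import numpy as np
import pytest

import amorphkin as ak


@pytest.fixture()
def config():
    return ak.StudyConfig()


@pytest.fixture(scope="session")
def neat_dsc_truth():
    """Neat-drug isothermal DSC conditions: n=3.8, tau_cr=55 min, t0=8800 s."""
    return ak.STUDY["dsc_neat"]


@pytest.fixture(scope="session")
def neat_dsc_curve(neat_dsc_truth):
    """Noiseless analytic Avrami curve at the neat-drug DSC conditions."""
    t = np.arange(0.0, 30000.0, 5.0)
    alpha = ak.avrami_alpha(t, neat_dsc_truth.n, neat_dsc_truth.tau_cr_s,
                            neat_dsc_truth.t0_s)
    return ak.KineticCurve(time=t, alpha=alpha)


@pytest.fixture(scope="session")
def alpha_spectral_truth():
    """Single structural HN process with dc conductivity (supercooled liquid)."""
    return ak.SpectralTruth(
        processes=(ak.HNProcess(delta_eps=8.9, tau_hn=1e-4, a=0.85, b=0.55),),
        eps_inf=3.0,
        sigma_dc=1e-10,
    )
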