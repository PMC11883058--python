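import numpy as np
import pytest

from canopyresp.forcing import ClimatologyParams, generate_forcing
from canopyresp.experiment import RunConfig, preset_pfts, run_coexistence, run_gradient_ensemble
from canopyresp.physiology import PFTParams


@pytest.fixture(scope="session")
def pfts():
    return preset_pfts()


@pytest.fixture(scope="session")
def tropical_pft(pfts):
    return pfts["broadleaf_evergreen_tropical"]


@pytest.fixture(scope="session")
def quiet_year():
    """One year of noise-free tropical forcing (deterministic sinusoids)."""
    params = ClimatologyParams(noise_sd_temp=0.0, noise_sd_par=0.0, seed=0)
    return generate_forcing(params, 1)


@pytest.fixture(scope="session")
def noisy_forcing():
    """Three years of the default stochastic tropical preset."""
    return generate_forcing(ClimatologyParams(seed=7), 3)


@pytest.fixture(scope="session")
def ensemble_150yr(pfts):
    """The full 150-yr single-PFT gradient ensemble (shared by the
    equilibrium-ordering and conservation checks)."""
    cfg = RunConfig(
        pfts={"broadleaf_evergreen_tropical": pfts["broadleaf_evergreen_tropical"]},
        climate=ClimatologyParams(),
        years=150,
        seed=1,
    )
    return run_gradient_ensemble(cfg, quiet=True)


@pytest.fixture(scope="session")
def coexistence_300yr(pfts):
    """The paired 300-yr two-PFT runs under the default (V3) and a steep
    (V7) respiration gradient."""
    cfg = RunConfig(
        pfts={n: pfts[n] for n in ("light_demander", "shade_tolerant")},
        climate=ClimatologyParams(),
        years=300,
        seed=1,
        light_demander="light_demander",
        scenario_labels=["V3", "V7"],
    )
    return run_coexistence(cfg, quiet=True)
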