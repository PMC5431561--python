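import numpy as np
import pytest

from shotspike import (
    DeltaDist,
    ExponentialDist,
    NeuronParams,
    TruncGaussDist,
    UniformDist,
    build,
    solve_drive,
)

# common magnitude |a_p| = sigma_G calibrated so the truncated-Gaussian mean
# amplitude is -1 mV
TGD_CAL = 0.7766


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def families():
    """The four inhibitory laws at matched mean magnitude <|a_i|> = 1 mV."""
    return {
        "DD": DeltaDist(a_i=-1.0),
        "UD": UniformDist(l1=-2.0, l2=0.0),
        "TGD": TruncGaussDist(a_p=-TGD_CAL, sigma_G=TGD_CAL),
        "ED": ExponentialDist(a_scale=1.0, sign=-1),
    }


def make_lf(mu_T, sigma2, dist, neuron=NeuronParams(), drive_kind="dc"):
    sol = solve_drive(mu_T, sigma2, dist, neuron, drive_kind=drive_kind)
    return build(neuron, sol.drive, sol.inhibition), sol


@pytest.fixture(scope="session")
def dd_reference(neuron):
    """Workhorse configuration: delta kicks of 1 mV at mu_T=9, sigma^2=2."""
    lf, sol = make_lf(9.0, 2.0, DeltaDist(a_i=-1.0), neuron)
    return lf
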