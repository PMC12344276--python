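"""Shared fixtures: default parameter sets and small scenario builders."""

import dataclasses

import pytest

from chirosim import DEFAULT_PARAMS, PopulationParams, Scenario

#: The calibrated population-level triple used as ground truth throughout.
THETA_STAR = (1045.0, 0.29, 2.3)


@pytest.fixture(scope="session")
def deb_params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def deb_params_no_scatter():
    """Default DEB set with individual variability switched off."""
    return dataclasses.replace(DEFAULT_PARAMS, sigma_pAm=0.0)


@pytest.fixture(scope="session")
def pop_params():
    ks, a, fc = THETA_STAR
    return PopulationParams(KS=ks, a=a, FC=fc)


@pytest.fixture
def beaker_scenario():
    """A standard 20-larvae, 50 cm^2 beaker at the reference ration."""
    def make(ration=0.5, n=20, duration=None, **kw):
        kw.setdefault("stop_no_emergence_d",
                      7.0 if duration is None else None)
        return Scenario(name=f"beaker_{ration}_{n}", vessel_area_cm2=50.0,
                        n_initial=n, ration_mg=ration, duration_d=duration,
                        **kw)
    return make
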