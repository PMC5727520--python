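"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

import hpmrsi as hp
from hpmrsi.cohort import lesion_for_hemisphere_elevation


@pytest.fixture(scope="session")
def config() -> hp.AcquisitionConfig:
    return hp.AcquisitionConfig()


@pytest.fixture(scope="session")
def base_params() -> hp.KineticParams:
    return hp.KineticParams(kpl_per_s=0.02)


@pytest.fixture(scope="session")
def lesion_phantom(config, base_params) -> hp.TissuePhantom:
    """Phantom whose lesion elevates the injured-hemisphere ratio by 40%."""
    lesion = lesion_for_hemisphere_elevation(config, base_params, 40.0)
    return hp.make_phantom(grid_side=config.n_phase_encodes, lesion=lesion,
                           base_params=base_params)


@pytest.fixture(scope="session")
def noiseless_data(lesion_phantom, config) -> hp.DynamicCSIData:
    return hp.synthesize_kspace(lesion_phantom, config, noise_sd=0.0)


def two_site_expm_oracle(params: hp.KineticParams, times: np.ndarray) -> np.ndarray:
    """Matrix-exponential closed form of the piecewise-constant-input system.

    Augments the 2x2 linear exchange/relaxation system with a constant
    state driving the bolus input and propagates with scipy.linalg.expm —
    an implementation route independent of the package's analytic
    propagator.  Returns an array (len(times), 2) of (pyruvate, lactate).
    """
    kpl, r1p, r1l = params.kpl_per_s, params.r1p_per_s, params.r1l_per_s
    edges = (params.bolus_start_s, params.bolus_start_s + params.bolus_duration_s)
    state = np.array([0.0, 0.0, 1.0])
    out = np.empty((len(times), 2))
    t_prev = 0.0
    for i, t in enumerate(times):
        cuts = [t_prev] + [e for e in edges if t_prev < e < t] + [t]
        for a, b in zip(cuts[:-1], cuts[1:]):
            u = params.bolus_amplitude if edges[0] <= a < edges[1] else 0.0
            gen = np.array([[-(kpl + r1p), 0.0, u], [kpl, -r1l, 0.0], [0.0, 0.0, 0.0]])
            state = expm(gen * (b - a)) @ state
        out[i] = state[:2]
        t_prev = t
    return out
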