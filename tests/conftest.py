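"""Shared fixtures: a noiseless study configuration, its input function, and
reference kinetic parameters used across the suite."""

import numpy as np
import pytest

from petkin.blood import build_mcaif
from petkin.kinetic import CompartmentParams
from petkin.synthetic import RegionTruth, StudyConfig, make_input_function


@pytest.fixture(scope="session")
def clean_config() -> StudyConfig:
    """Noiseless single-truth config: no noise, no subject/session variability."""
    return StudyConfig(
        n_subjects=1,
        noise_scale=0.0,
        pf_jitter_sd=0.0,
        session_k1_sd=0.0,
        subject_k1_sd=0.0,
        subject_vnd_sd=0.0,
        subject_bp_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_config_4h(clean_config) -> StudyConfig:
    return StudyConfig(**{**clean_config.__dict__, "duration": "4h"})


@pytest.fixture(scope="session")
def input_function(clean_config):
    blood, _ = make_input_function(clean_config, subject=0, seed=1)
    return build_mcaif(blood, clean_config.pf_truth)


@pytest.fixture(scope="session")
def input_function_4h(clean_config_4h):
    blood, _ = make_input_function(clean_config_4h, subject=0, seed=1)
    return build_mcaif(blood, clean_config_4h.pf_truth)


@pytest.fixture(scope="session")
def reference_2t_params() -> CompartmentParams:
    """Reversible grey-matter-like kinetics (V_T ≈ 16.3 mL/cm³)."""
    return CompartmentParams(K1=0.37, k2=0.047, k3=0.03, k4=0.028)


@pytest.fixture
def single_region_config(clean_config) -> StudyConfig:
    """One-region clean config (fast displacement/ODE simulations)."""
    return StudyConfig(
        **{
            **clean_config.__dict__,
            "regions": (RegionTruth("striatum", 0.37, 1.07),),
        }
    )


def ode_tissue_oracle(params, input_function, frames, rtol=1e-10, atol=1e-12):
    """Independent stiff-ODE integration of the two-compartment mass balance.

    Solves dCf/dt = K1 Cp - (k2+k3) Cf + k4 Cb, dCb/dt = k3 Cf - k4 Cb and
    returns frame averages on a dense output grid.  Used as the oracle for
    the analytic convolution; shares no code with the implementation path.
    """
    from scipy.integrate import solve_ivp

    t_end = float(frames.end_times[-1])
    grid = np.linspace(0.0, t_end, int(t_end / 0.01) + 1)

    def rhs(t, y):
        cp = input_function.interpolate(t)
        cf, cb = y
        return [
            params.K1 * cp - (params.k2 + params.k3) * cf + params.k4 * cb,
            params.k3 * cf - params.k4 * cb,
        ]

    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], t_eval=grid, method="LSODA",
                    rtol=rtol, atol=atol, max_step=0.5)
    ct = sol.y.sum(axis=0)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (ct[1:] + ct[:-1]) * np.diff(grid))])
    i0 = np.interp(frames.start_times, grid, cum)
    i1 = np.interp(frames.end_times, grid, cum)
    return (i1 - i0) / frames.durations
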