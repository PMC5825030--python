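"""Shared fixtures: reference network, tiny test systems, small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ctbolus.cohort import CohortSpec, TruthParameters, generate_cohort
from ctbolus.pbpk import (CompartmentSpec, ContrastAgent, InjectionProtocol,
                          PBPKNetwork, build_reference_network)
from ctbolus.transport import SolverSettings


@pytest.fixture(scope="session")
def reference_network():
    return build_reference_network()


@pytest.fixture(scope="session")
def saline_like_agent():
    """Agent with the reference's osmotic/viscous properties (identity scaling)."""
    return ContrastAgent("ref-like", 370.0, 9.1, osmotic_ratio=2.76)


def make_tank_loop(q_ml_min: float, v_ml: float, n_sub: int,
                   buffer_volume: float = 1e7) -> PBPKNetwork:
    """A single test compartment closed through an enormous buffer.

    The buffer's transit time (volume / flow) is orders of magnitude
    beyond any test horizon, so the tank sees effectively no
    recirculation and its impulse response can be compared with the
    open-loop tanks-in-series closed form.
    """
    comps = (
        CompartmentSpec("tank", blood_flow=q_ml_min, v_iv=v_ml,
                        n_sub=n_sub),
        CompartmentSpec("buffer", blood_flow=q_ml_min, v_iv=buffer_volume,
                        n_sub=1),
    )
    edges = (("tank", "buffer", q_ml_min), ("buffer", "tank", q_ml_min))
    return PBPKNetwork(compartments=comps, edges=edges,
                       injection_site="tank")


@pytest.fixture()
def tank_loop():
    return make_tank_loop


@pytest.fixture(scope="session")
def zero_volume_protocol(saline_like_agent):
    """No injected contrast: used for impulse-response studies."""
    return InjectionProtocol(cm_volume=0.0, agent=saline_like_agent,
                             injection_rate=4.0)


@pytest.fixture(scope="session")
def small_clean_cohort():
    """Six zero-noise synthetic patients generated at the default truth."""
    spec = CohortSpec(n_patients=6, seed=11, n_calibration=6,
                      hu_noise_sd=0.0, jitter_sd=0.0)
    return generate_cohort(spec, TruthParameters())


@pytest.fixture(scope="session")
def calib_settings():
    return SolverSettings(horizon=80.0)
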