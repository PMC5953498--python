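import numpy as np
import pytest

import dtjsub as dj
from dtjsub import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def rect_grid():
    return dj.make_grid((64, 64), 2.5, "full", thickness_mm=1600.0)


@pytest.fixture(scope="session")
def opposite_electrodes(rect_grid):
    return dj.make_electrodes(rect_grid, [
        {"kind": "edge", "edge": "left", "polarity": +1},
        {"kind": "edge", "edge": "right", "polarity": -1}], current_mA=2.0)


@pytest.fixture(scope="session")
def default_result():
    """One full zero-noise pipeline run shared by the reconstruction tests."""
    return run_pipeline(RunConfig(recon_n_max=5))


@pytest.fixture(scope="session")
def anis_phantom(rect_grid):
    """Concentric-fiber diffusion tensor + partial-volume 2:1 eta inclusion."""
    D, eta = dj.make_phantom(
        rect_grid,
        {"pattern": "concentric", "eigenvalues": (1.7e-3, 0.3e-3, 0.3e-3)},
        {"background": 0.5, "edge_smooth": 1.0,
         "inclusions": [{"center": (40, 40), "radius": 8, "eta": 0.25}]},
        seed=0)
    return D, eta


@pytest.fixture(scope="session")
def forward_truth(rect_grid, opposite_electrodes, anis_phantom):
    """True conductivity, potential and current of the shared phantom."""
    D, eta = anis_phantom
    C = dj.ConductivityTensorField.from_eta_and_diffusion(eta, D)
    u = dj.solve_potential(C, opposite_electrodes, rect_grid)
    J = dj.compute_current_density(C, u, rect_grid,
                                   electrodes=opposite_electrodes)
    return {"C": C, "u": u, "J": J, "D": D, "eta": eta}


@pytest.fixture(scope="session")
def exp_phantom(rect_grid):
    D, eta = dj.make_phantom(
        rect_grid,
        {"pattern": "parallel", "angle_deg": 30.0,
         "eigenvalues": (1.7e-3, 0.3e-3, 0.3e-3)},
        {"kind": "exponential", "eta0": 0.5, "ax": 0.6, "ay": -0.4},
        seed=0)
    C = dj.ConductivityTensorField.from_eta_and_diffusion(eta, D)
    currents = []
    for spec in ([{"kind": "edge", "edge": "left", "polarity": +1},
                  {"kind": "edge", "edge": "right", "polarity": -1}],
                 [{"kind": "edge", "edge": "top", "polarity": +1},
                  {"kind": "edge", "edge": "bottom", "polarity": -1}]):
        el = dj.make_electrodes(rect_grid, spec, current_mA=2.0)
        u = dj.solve_potential(C, el, rect_grid)
        currents.append(dj.compute_current_density(C, u, rect_grid,
                                                   electrodes=el))
    return D, eta, currents
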