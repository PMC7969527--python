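from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import qamrm as qm

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def design_q():
    """The bundled 14-item, 3-attribute recovery design."""
    return qm.recovery_design_qmatrix()


@pytest.fixture(scope="session")
def full_space():
    return qm.enumerate_profiles(3)


@pytest.fixture(scope="session")
def expected_levels():
    """Reference level matrices (items x 8 classes) for both anchoring modes."""
    out = {}
    for mode in ("noncompensatory", "compensatory"):
        frame = pd.read_csv(DATA_DIR / f"levels_{mode}.csv", index_col=0)
        out[mode.replace("noncompensatory", "non_compensatory")] = frame.to_numpy()
    return out


@pytest.fixture(scope="session")
def small_fit(design_q, full_space):
    """One moderately sized converged fit shared by several tests."""
    truth = qm.recovery_truth("non_compensatory")
    y, classes, thetas = qm.simulate_dataset(truth, 800, seed=11)
    cfg = qm.FitConfig(
        n_starts=4, burn_iters=6, n_survivors=2, n_quadrature=21, seed=5
    )
    fit = qm.fit_em(y, design_q, full_space, "non_compensatory", cfg=cfg)
    return {"fit": fit, "y": y, "classes": classes, "thetas": thetas,
            "truth": truth}


def brute_force_class_loglik(y, params, layout, n_grid=10001, half_width=8.0):
    """Trapezoid-rule oracle for the class-conditional log marginal likelihood.

    Integrates the Rasch response likelihood against the N(0, sd^2) ability
    density on a dense grid over [-8 sd, 8 sd]; independent of the quadrature
    code path it checks.
    """
    from scipy.special import expit

    sd = params.ability_sd
    theta = np.linspace(-half_width * sd, half_width * sd, n_grid)
    dens = np.exp(-0.5 * (theta / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    B = params.difficulties[layout.slot_of]  # (J, G)
    N, J = y.values.shape
    G = B.shape[1]
    out = np.empty((N, G))
    mask = ~np.isnan(y.values)
    for i in range(N):
        obs = mask[i]
        yi = y.values[i, obs]
        for g in range(G):
            p = expit(theta[:, None] - B[obs, g][None, :])
            lik = np.prod(np.where(yi[None, :] == 1.0, p, 1.0 - p), axis=1)
            out[i, g] = np.log(np.trapezoid(lik * dens, theta))
    return out
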