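import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from crossomix import synthdata as sd


def brute_force_glasso(S, lam):
    """Generic-optimizer oracle for the penalized precision estimate:
    trust-constr with analytic gradient on (vech Theta, |.| auxiliaries),
    independent of the coordinate-descent path."""
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    m = len(iu[0])

    def unpack(x):
        T = np.zeros((p, p))
        T[np.diag_indices(p)] = x[:p]
        T[iu] = x[p : p + m]
        return T + T.T - np.diag(np.diag(T)), x[p + m :]

    def obj(x):
        T, t = unpack(x)
        sign, ld = np.linalg.slogdet(T)
        if sign <= 0:
            return 1e6
        # penalty sums over ordered pairs j != k -> 2 lam per upper pair
        return -(ld - np.trace(S @ T)) + 2 * lam * t.sum()

    def jac(x):
        T, t = unpack(x)
        G = -(np.linalg.inv(T) - S)
        out = np.empty_like(x)
        out[:p] = np.diag(G)
        out[p : p + m] = 2.0 * G[iu]
        out[p + m :] = 2.0 * lam
        return out

    A = np.zeros((2 * m, p + 2 * m))
    for i in range(m):
        A[2 * i, p + i] = -1
        A[2 * i, p + m + i] = 1
        A[2 * i + 1, p + i] = 1
        A[2 * i + 1, p + m + i] = 1
    lc = optimize.LinearConstraint(A, 0, np.inf)
    T0 = np.linalg.inv(S)
    x0 = np.concatenate([np.diag(T0), T0[iu], np.abs(T0[iu]) + 0.05])
    res = optimize.minimize(
        obj, x0, jac=jac, method="trust-constr", constraints=[lc],
        options={"maxiter": 10000, "gtol": 1e-14, "xtol": 1e-16},
    )
    T, _ = unpack(res.x)
    return T


@pytest.fixture(scope="session")
def glasso_oracle():
    return brute_force_glasso


@pytest.fixture(scope="session")
def small_design():
    """20-participant crossover design (120 profiles)."""
    return sd.generate_design(sd.DesignConfig(n_participants=20, seed=101))


@pytest.fixture(scope="session")
def small_exposures(small_design):
    return sd.generate_exposures(small_design, sd.ExposureModel(), seed=102)


@pytest.fixture(scope="session")
def small_study(small_design, small_exposures):
    """Feature table with 2 affected features, batch effects and censoring."""
    theta, edges = sd.generate_precision_matrix(
        sd.PrecisionSpec(p=25, density=0.15), seed=103
    )
    effects = sd.EffectSpec(affected=[0, 1], beta=0.02, pollutant="NO2")
    matrix, truth = sd.generate_omics(
        small_design,
        small_exposures,
        theta,
        effects,
        batch_sd=0.4,
        censor_fraction=0.1,
        seed=104,
    )
    truth["edges"] = edges
    return matrix, truth
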