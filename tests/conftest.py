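import numpy as np
import pytest

from scaledcm.dcm import DCMResults, PriorSpec


@pytest.fixture(scope="session")
def orbit_family():
    """Ten-scale three-body family (shared: the simulation is the slow part)."""
    from scaledcm.orbits import kepler_system, make_orbit_family

    return make_orbit_family(
        kepler_system(), n_scales=10, increment=0.10, dt=0.05, n_periods=6.0
    )


def make_posterior(A, sd=0.05, F=0.0, rho=0.0):
    """Hand-built Gaussian posterior over all elements of A (default priors)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    priors = PriorSpec.default(n)
    d = n * n
    cov = sd**2 * ((1 - rho) * np.eye(d) + rho * np.ones((d, d)))
    return DCMResults(
        mean_A=A,
        mean_C=np.zeros((n, 0)),
        cov=cov,
        free_energy=F,
        converged=True,
        n_iter=1,
        priors=priors,
        free_A=priors.var_A > 0,
        free_C=np.zeros((n, 0), dtype=bool),
        method="synthetic",
    )
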