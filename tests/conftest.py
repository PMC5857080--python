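import numpy as np
import pytest

from rsmdeg import fit_quadratic, load_fixture


@pytest.fixture(scope="session")
def adl15():
    return load_fixture("table2_adl15")


@pytest.fixture(scope="session")
def adl36():
    return load_fixture("table4_adl36")


@pytest.fixture(scope="session")
def adl15_fit(adl15):
    return fit_quadratic(adl15.design, adl15.response)


@pytest.fixture(scope="session")
def adl36_fit(adl36):
    return fit_quadratic(adl36.design, adl36.response)


@pytest.fixture(scope="session")
def factors():
    return load_fixture("table1_factors")


def random_quadratic(rng, k, concave=False):
    """Random QuadraticFit for property tests; optionally forced concave."""
    from rsmdeg import QuadraticFit

    n_int = k * (k - 1) // 2
    beta_lin = rng.normal(0, 3, k)
    if concave:
        # negative-definite Hessian: -(A A' + eps I) with small off-diagonals
        A = rng.normal(0, 1, (k, k))
        H = -(A @ A.T + 0.5 * np.eye(k))
        beta_quad = np.diag(H).copy()
        beta_int = np.array([2 * H[i, j] for i in range(k)
                             for j in range(i + 1, k)])
    else:
        beta_quad = rng.normal(0, 2, k)
        beta_int = rng.normal(0, 1, n_int)
    return QuadraticFit(k=k, beta0=float(rng.normal(0, 10)),
                        beta_lin=beta_lin, beta_quad=beta_quad,
                        beta_int=beta_int)
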