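import numpy as np
import pytest

from xlinkforge import synthetic_data as sd


@pytest.fixture(scope="session")
def diatomic():
    """(geom, ff, hessian) for the minimal one-bond molecule."""
    return sd.make_toy_molecule(sd.diatomic_recipe(k=1000.0, b0=0.10))


@pytest.fixture(scope="session")
def water_like():
    return sd.make_toy_molecule(sd.water_like_recipe())


@pytest.fixture(scope="session")
def chain5():
    return sd.make_toy_molecule(sd.chain5_recipe())


@pytest.fixture(scope="session")
def crosslink_fixture():
    return sd.make_crosslink_fixture("DOGDIC-like", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def finite_difference_hessian(energy, coords, step=1e-5):
    """Central-difference Hessian oracle on an energy callable of (N, 3)."""
    x0 = np.asarray(coords, dtype=float).ravel()
    n = len(x0)
    h = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
            xpp[a] += step
            xpp[b] += step
            xpm[a] += step
            xpm[b] -= step
            xmp[a] -= step
            xmp[b] += step
            xmm[a] -= step
            xmm[b] -= step
            val = (
                energy(xpp.reshape(-1, 3))
                - energy(xpm.reshape(-1, 3))
                - energy(xmp.reshape(-1, 3))
                + energy(xmm.reshape(-1, 3))
            ) / (4 * step * step)
            h[a, b] = h[b, a] = val
    return h
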