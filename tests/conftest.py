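"""Shared fixtures for the spinpair test suite."""

import numpy as np
import pytest

from spinpair.systems import (
    ElectronSpin,
    HyperfineNucleus,
    PairCoupling,
    SpinSystem,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pair(J=0.0, D=0.0, theta=0.0, a13C=None, g=2.0035, mw=9.4):
    """Two coupled electrons, optionally with a single 13C on the first."""
    nuclei = []
    if a13C is not None:
        nuclei = [HyperfineNucleus(isotope="13C", a_iso=a13C, attached_to=0)]
    return SpinSystem(
        electrons=[ElectronSpin("A", g_iso=g), ElectronSpin("B", g_iso=g)],
        nuclei=nuclei,
        couplings=[PairCoupling(spins=(0, 1), J=J, D=D, theta=theta)],
        mw_frequency=mw,
    )


@pytest.fixture
def pair_factory():
    return make_pair


@pytest.fixture
def monoradical_system():
    return SpinSystem(
        electrons=[ElectronSpin("mono")],
        nuclei=[HyperfineNucleus(isotope="1H", a_iso=0.3, n_equivalent=6)],
        couplings=[],
    )
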