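"""Powder averaging, Pake-pattern closed forms and singularity extraction."""

import numpy as np
import pytest

from spinpair.powder import (
    ExtractionError,
    MixtureModel,
    PowderGrid,
    RegimeError,
    dipolar_splitting,
    pake_singularities,
    powder_sticks,
    simulate_powder,
)
from spinpair.spectrum import LineShape
from spinpair.systems import ElectronSpin, SpinSystem, ValidationError

from conftest import make_pair

LS = LineShape(gaussian_width=0.3, lorentzian_width=0.1)


class TestGrid:
    def test_weights_sum_to_one(self):
        g = PowderGrid(n_theta=64)
        assert g.weights.sum() == pytest.approx(1.0)
        assert np.all((g.nodes >= 0) & (g.nodes <= 1))

    def test_spherical_product_grid(self):
        g = PowderGrid(n_theta=8, n_phi=16)
        dirs, wts = g.orientations()
        assert dirs.shape == (128, 3)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        assert wts.sum() == pytest.approx(1.0)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            PowderGrid(n_theta=1)


class TestClosedForms:
    def test_weak_coupling_doublet(self):
        # theta = 90 deg: d = D; doublet offset |D + J| / 2 (J signed)
        out = dipolar_splitting(np.pi / 2, D=10.0, J=2.0, regime="weak")
        assert np.allclose(out, [6.0])
        out_neg = dipolar_splitting(np.pi / 2, D=10.0, J=-2.0, regime="weak")
        assert np.allclose(out_neg, [4.0])

    def test_strong_coupling_three_halves(self):
        out = dipolar_splitting(np.pi / 2, D=10.0, J=100.0, regime="strong")
        assert np.allclose(out, [7.5])

    def test_intermediate_raises(self):
        with pytest.raises(RegimeError, match="full"):
            dipolar_splitting(0.5, D=10.0, J=20.0, regime="intermediate")

    def test_full_converges_to_weak(self):
        # both electrons' doublets collapse onto the weak offset |d + J| / 2
        want = dipolar_splitting(0.3, D=10.0, J=5.0, regime="weak")
        got = dipolar_splitting(0.3, D=10.0, J=5.0, regime="full", delta_omega=1e4)
        assert np.allclose(got, want, atol=1e-2)

    def test_full_converges_to_strong(self):
        want = dipolar_splitting(0.3, D=10.0, J=200.0, regime="strong")
        got = dipolar_splitting(0.3, D=10.0, J=200.0, regime="full", delta_omega=1e-9)
        assert np.allclose(got, want, atol=1e-6)


@pytest.fixture(scope="module")
def weak_pake():
    """Weak-coupling Pake pattern, J = 0, D = 10 MHz.

    Identical electrons at J = 0 sit in the strong regime (delta_omega = 0),
    so one electron is detuned far beyond D by a spectator nucleus; the
    undetuned electron's doublet then realizes the weak pattern."""
    sys_ = make_pair(J=0.0, D=10.0, a13C=2000.0)
    axis = np.linspace(-25.0, 25.0, 4096)
    return simulate_powder(sys_, PowderGrid(n_theta=256), LS, axis)


class TestPowderSpectra:
    def test_pake_singularities_weak(self, weak_pake):
        """nu_perp = D/2, nu_par = D at J = 0 (criterion 8 invariant)."""
        nu_perp, nu_par = pake_singularities(weak_pake)
        assert nu_perp == pytest.approx(5.0, abs=0.15)
        assert nu_par == pytest.approx(10.0, abs=0.5)
        assert nu_par / nu_perp == pytest.approx(2.0, abs=0.1)

    def test_grid_convergence(self):
        """Doubling n_theta changes the spectrum by < 0.5% (criterion 8)."""
        sys_ = make_pair(J=0.0, D=10.0)
        sys_.nuclei = []
        axis = np.linspace(-25.0, 25.0, 2048)
        s1 = simulate_powder(sys_, PowderGrid(n_theta=256), LS, axis)
        s2 = simulate_powder(sys_, PowderGrid(n_theta=512), LS, axis)
        rel = np.max(np.abs(s1.intensity - s2.intensity)) / np.max(np.abs(s2.intensity))
        assert rel < 0.005

    def test_D_zero_is_orientation_independent(self):
        sys_ = make_pair(J=0.0, D=0.0)
        sys_.nuclei = []
        pos, wt = powder_sticks(sys_, PowderGrid(n_theta=32))
        assert np.ptp(pos) < 1e-9  # all orientations coincide

    def test_mixture_linearity(self):
        bi = make_pair(J=0.0, D=10.0)
        bi.nuclei = []
        mono = SpinSystem(electrons=[ElectronSpin("m")], mw_frequency=9.4)
        axis = np.linspace(-25.0, 25.0, 2048)
        grid = PowderGrid(n_theta=64)
        s_bi = simulate_powder(bi, grid, LS, axis)
        s_mono = simulate_powder(mono, grid, LS, axis)
        frac = 0.15
        s_mix = simulate_powder(
            MixtureModel([(bi, 1 - frac), (mono, frac)]), grid, LS, axis
        )
        # components are normalized to unit summed transition weight, so the
        # mixture is exactly the fraction-weighted sum of the component traces
        want = (1 - frac) * s_bi.intensity + frac * s_mono.intensity
        assert np.allclose(s_mix.intensity, want, atol=1e-9 * _norm(s_mix))

    def test_fractions_must_sum_to_one(self):
        bi = make_pair()
        with pytest.raises(ValidationError):
            MixtureModel([(bi, 0.5), (bi, 0.2)]).validate()

    def test_three_spin_broader_than_two_spin(self):
        """The tris-radical pattern spreads intensity wider than one pair."""
        from spinpair.synthetic import make_fixture

        axis = np.linspace(-25.0, 25.0, 1024)
        grid = PowderGrid(n_theta=32)
        f3 = make_fixture("3a")
        f2 = make_fixture("2a")
        s3 = simulate_powder(f3.frozen_system, grid, LS, axis)
        s2 = simulate_powder(f2.frozen_system, grid, LS, axis)

        def spread(spec):
            a = spec.absorption().intensity
            a = np.clip(a, 0.0, None)
            return np.sqrt(np.sum(a * axis**2) / np.sum(a))

        assert spread(s3) > spread(s2)


class TestExtraction:
    def test_extraction_error_on_featureless_trace(self):
        from spinpair.spectrum import Spectrum

        axis = np.linspace(-10.0, 10.0, 1001)
        flat = Spectrum(axis, np.gradient(np.exp(-axis**2 / 50.0), axis))
        with pytest.raises(ExtractionError):
            pake_singularities(flat)

    def test_noisy_extraction_close_to_noiseless(self, weak_pake):
        """SNR 50 noise moves the singularities by < 1 kernel width.

        The parallel edge carries only ~1% of the derivative peak-to-peak
        amplitude, so heavier noise makes it statistically undetectable by
        any estimator; SNR 50 matches the synthetic-data noise level."""
        clean_perp, clean_par = pake_singularities(weak_pake)
        width = max(LS.gaussian_width, LS.lorentzian_width)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = weak_pake.copy_with(
                intensity=weak_pake.intensity
                + rng.normal(0, 0.02 * np.ptp(weak_pake.intensity),
                             weak_pake.intensity.shape)
            )
            nu_perp, nu_par = pake_singularities(noisy)
            assert abs(nu_perp - clean_perp) < width
            assert abs(nu_par - clean_par) < 2 * width


def _norm(spec):
    return np.max(np.abs(spec.intensity))
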