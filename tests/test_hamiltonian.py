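"""Hamiltonian construction, exact diagonalization and its closed-form oracles."""

import numpy as np
import pytest

from spinpair.hamiltonian import (
    INTENSITY_FLOOR,
    TransitionSet,
    batched_transitions,
    build_hamiltonian,
    classify_regime,
    dipolar_secular_coefficient,
    effective_satellite_splitting,
    transitions,
)
from spinpair.systems import MHZ_PER_MT, ValidationError

from conftest import make_pair


def ab_quartet(J, delta_nu):
    """Closed-form AB line offsets from the centre: +/- (C +/- J/2)."""
    C = 0.5 * np.sqrt(delta_nu**2 + J**2)
    return np.sort([-(C + J / 2), -(C - J / 2), C - J / 2, C + J / 2])


class TestHamiltonianStructure:
    @pytest.mark.parametrize("J,D,theta", [(0, 0, 0), (77, 7, 0.3), (-30, 2, 1.2)])
    def test_hermitian(self, J, D, theta):
        sys_ = make_pair(J=J, D=D, theta=theta, a13C=31.25)
        H = build_hamiltonian(sys_, sys_.center_field_mT(), (0.5,))
        assert np.allclose(H, H.T)

    def test_three_electron_dimension(self):
        from spinpair.synthetic import make_fixture

        sys_ = make_fixture("3a").system
        sys_.nuclei = []
        H = build_hamiltonian(sys_, sys_.center_field_mT())
        assert H.shape == (8, 8)
        assert np.allclose(H, H.T)

    def test_config_length_mismatch_rejected(self):
        sys_ = make_pair(a13C=31.25)
        with pytest.raises(ValidationError):
            build_hamiltonian(sys_, 335.0, ())

    def test_dipolar_coefficient_magic_angle(self):
        theta_magic = np.arccos(1 / np.sqrt(3))
        assert dipolar_secular_coefficient(7.0, theta_magic) == pytest.approx(0.0, abs=1e-12)
        assert dipolar_secular_coefficient(7.0, 0.0) == pytest.approx(-14.0)
        assert dipolar_secular_coefficient(7.0, np.pi / 2) == pytest.approx(7.0)


class TestIntensityConservation:
    @pytest.mark.parametrize("J,D", [(0.0, 0.0), (77.0, 0.0), (0.0, 7.0),
                                     (75.0, 7.0), (-40.0, 3.0)])
    def test_total_intensity_independent_of_couplings(self, J, D):
        """Summed |<f|Sx|i>|^2 over all transitions equals Tr(Sx^2)/2."""
        sys_ = make_pair(J=J, D=D, theta=np.pi / 2, a13C=31.25)
        ts = transitions(sys_, nuclear_config=(0.5,), intensity_floor=0.0)
        # Tr(Sx^2)/2 = 1 for two S = 1/2 electrons (upper-triangle pair sum)
        assert ts.total_weight == pytest.approx(1.0, rel=1e-12)

    def test_floor_drops_forbidden_lines(self):
        sys_ = make_pair(J=75.0, a13C=31.25)
        ts_all = transitions(sys_, nuclear_config=(0.5,), intensity_floor=0.0)
        ts = transitions(sys_, nuclear_config=(0.5,))
        assert len(ts.frequencies) < len(ts_all.frequencies)


class TestABOracle:
    def test_quartet_against_closed_form_100_draws(self):
        """Criterion 7: positions match the AB closed form to 1e-9 MHz."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            J = rng.uniform(-150.0, 150.0)
            a = rng.uniform(0.5, 60.0)
            sys_ = make_pair(J=J, a13C=a)
            B0 = sys_.center_field_mT()
            nu0 = MHZ_PER_MT * 2.0035 * B0
            # a tiny relative floor keeps the weak outer AB lines but drops
            # the strictly forbidden zero-intensity pairs
            ts = transitions(sys_, B0, (0.5,), intensity_floor=1e-12)
            # the nuclear projection +1/2 shifts one electron by a/2, so the
            # AB centre sits at nu0 + a/4 with delta_nu = a/2
            got = np.sort(ts.frequencies - (nu0 + a / 4.0))
            want = ab_quartet(J, a / 2.0)
            assert np.max(np.abs(got - want)) < 1e-9

    def test_exactly_four_allowed_transitions(self):
        """Criterion 4 (t5): J = 75, a = 31.25, fixed projection -> 4 lines."""
        sys_ = make_pair(J=75.0, a13C=31.25)
        ts = transitions(sys_, nuclear_config=(0.5,))
        assert len(ts.frequencies) == 4


class TestBatched:
    def test_batched_matches_sequential(self):
        sys_ = make_pair(J=30.0, D=5.0, theta=1.0, a13C=25.0)
        B0 = sys_.center_field_mT()
        configs = [(-0.5,), (0.5,)]
        ts_b = batched_transitions(sys_, B0, configs, probs=[0.5, 0.5])
        seq_f = np.concatenate(
            [transitions(sys_, B0, c).frequencies for c in configs]
        )
        seq_w = 0.5 * np.concatenate(
            [transitions(sys_, B0, c).intensities for c in configs]
        )
        assert np.allclose(np.sort(ts_b.frequencies), np.sort(seq_f), atol=1e-10)
        assert np.allclose(np.sort(ts_b.intensities), np.sort(seq_w), atol=1e-12)


class TestMerge:
    def test_merged_combines_close_lines(self):
        ts = TransitionSet(np.array([10.0, 10.05, 20.0]), np.array([1.0, 1.0, 2.0]))
        m = ts.merged(tol=0.1)
        assert len(m.frequencies) == 2
        assert m.frequencies[0] == pytest.approx(10.025)
        assert m.total_weight == pytest.approx(4.0)


class TestRegime:
    def test_thresholds(self):
        assert classify_regime(1.0, 0.0, 15.625).regime == "weak"
        assert classify_regime(77.0, 0.0, 4.2).regime == "strong"
        assert classify_regime(30.0, 0.0, 15.625).regime == "intermediate"

    def test_exchange_dipolar_compensation(self):
        # J = D/2 cancels in the numerator whatever delta_omega
        assert classify_regime(3.5, 7.0, 0.001).regime == "weak"

    def test_zero_delta_omega_is_strong(self):
        rep = classify_regime(1.0, 0.0, 0.0)
        assert rep.regime == "strong"
        assert np.isinf(rep.ratio)


class TestSatelliteSplitting:
    def test_limits(self):
        a = 25.0
        assert effective_satellite_splitting(0.0, a) == pytest.approx(a, rel=1e-9)
        assert effective_satellite_splitting(1e5, a) == pytest.approx(a / 2, rel=1e-4)

    def test_closed_form(self):
        """Apparent splitting a/2 + sqrt(a^2/4 + J^2) - J for J >= 0."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            J = rng.uniform(0.0, 200.0)
            a = rng.uniform(1.0, 40.0)
            want = a / 2 + np.sqrt(a**2 / 4 + J**2) - J
            assert effective_satellite_splitting(J, a) == pytest.approx(want, abs=1e-9)

    def test_monotone_decreasing_in_J(self):
        a = 31.25
        vals = [effective_satellite_splitting(J, a) for J in np.linspace(0, 300, 61)]
        assert np.all(np.diff(vals) < 0)

    def test_strong_coupling_halving(self):
        """Criterion 3 (t4): J = 77 MHz, a = 0.3 MHz -> 0.15 MHz."""
        split = effective_satellite_splitting(77.0, 0.3)
        assert round(split, 2) == 0.15

    def test_zero_coupling_constant(self):
        assert effective_satellite_splitting(50.0, 0.0) == 0.0
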