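"""Isotropic spectra: multiplets, isotopomer statistics, 13C satellites."""

import numpy as np
import pytest
from scipy.signal import find_peaks
from scipy.special import comb

from spinpair.liquid import (
    C13_ABUNDANCE,
    C13_HFCC,
    SITE_CARBONS,
    enumerate_configs,
    group_projections,
    isotopomer_expansion,
    satellite_positions,
    simulate_isotropic,
    stick_spectrum,
)
from spinpair.spectrum import LineShape
from spinpair.systems import (
    ElectronSpin,
    HyperfineNucleus,
    SpinSystem,
    ValidationError,
)

from conftest import make_pair


class TestGroupProjections:
    def test_binomial_weights_six_protons(self):
        ms, probs = group_projections(HyperfineNucleus(a_iso=0.3, n_equivalent=6))
        assert np.allclose(ms, np.arange(-3.0, 3.5, 1.0))
        want = np.array([comb(6, k) for k in range(7)]) / 64.0
        assert np.allclose(probs, want)

    def test_spin_one_triangle(self):
        ms, probs = group_projections(
            HyperfineNucleus(a_iso=1.0, spin_quantum_number=1.0, n_equivalent=2)
        )
        assert np.allclose(ms, [-2, -1, 0, 1, 2])
        assert np.allclose(probs, np.array([1, 2, 3, 2, 1]) / 9.0)

    def test_probabilities_normalized(self):
        for n in (1, 3, 7):
            _, probs = group_projections(HyperfineNucleus(a_iso=1.0, n_equivalent=n))
            assert probs.sum() == pytest.approx(1.0)


class TestIsotopomers:
    def test_weights_close_to_one(self):
        sys_ = make_pair(J=77.0)
        comps = isotopomer_expansion(sys_)
        total = sum(c.weight for c in comps)
        # all-12C + single-13C should capture all but the multi-13C remainder
        p, N = C13_ABUNDANCE, 2 * sum(SITE_CARBONS.values())
        want = (1 - p) ** N + N * p * (1 - p) ** (N - 1)
        assert total == pytest.approx(want, rel=1e-12)
        assert total > 0.94

    def test_single_site_weight_formula(self):
        sys_ = make_pair()
        comps = isotopomer_expansion(sys_)
        p, N = C13_ABUNDANCE, 2 * sum(SITE_CARBONS.values())
        by_site = {c.site: c.weight for c in comps if c.site}
        for site, n in SITE_CARBONS.items():
            assert by_site[site] == pytest.approx(2 * n * p * (1 - p) ** (N - 1))

    def test_zero_abundance_only_parent(self):
        comps = isotopomer_expansion(make_pair(), abundance=0.0)
        assert len(comps) == 1 and comps[0].site is None
        assert comps[0].weight == 1.0

    def test_unreasonable_abundance_rejected(self):
        with pytest.raises(ValidationError):
            isotopomer_expansion(make_pair(), abundance=0.5)


class TestStickSpectrum:
    def test_monoradical_seven_line_binomial(self, monoradical_system):
        pos, wt = stick_spectrum(monoradical_system)
        # merge sticks by position
        uniq = {}
        for p, w in zip(np.round(pos, 6), wt):
            uniq[p] = uniq.get(p, 0.0) + w
        positions = np.array(sorted(uniq))
        weights = np.array([uniq[p] for p in positions])
        assert np.allclose(positions, 0.3 * np.arange(-3, 4), atol=1e-9)
        assert np.allclose(weights / weights.min(), [1, 6, 15, 20, 15, 6, 1], rtol=1e-9)

    def test_strong_coupling_halved_splitting(self):
        """J >> a: multiplet lines spaced by a/2 instead of a."""
        sys_ = make_pair(J=77.0)
        for k in range(2):
            sys_.nuclei.append(
                HyperfineNucleus(isotope="1H", a_iso=0.3, n_equivalent=6, attached_to=k)
            )
        pos, wt = stick_spectrum(sys_)
        # central multiplet only: the weak outer AB lines sit near +/- J
        keep = np.abs(pos) < 2.0
        pos, wt = pos[keep], wt[keep]
        order = np.argsort(pos)
        pos, wt = pos[order], wt[order]
        # cluster sticks separated by less than half the expected spacing
        splits = np.where(np.diff(pos) > 0.075)[0] + 1
        centres = [np.average(p, weights=w) for p, w in
                   zip(np.split(pos, splits), np.split(wt, splits))]
        assert len(centres) == 13  # 12 equivalent-feeling protons -> 13 lines
        assert np.allclose(np.diff(centres), 0.15, atol=0.01)

    def test_enumerate_configs_weights_sum_to_one(self):
        sys_ = make_pair(J=10.0, a13C=25.0)
        sys_.nuclei.append(HyperfineNucleus(a_iso=0.3, n_equivalent=4, attached_to=1))
        configs, probs = enumerate_configs(sys_)
        assert len(configs) == 2 * 5
        assert probs.sum() == pytest.approx(1.0)


class TestSatellites:
    def test_satellite_splitting_limits(self):
        s0 = satellite_positions("ortho", 0.0)
        assert s0["splitting"] == pytest.approx(25.0, rel=1e-9)
        s_inf = satellite_positions("ortho", 1e5)
        assert s_inf["splitting"] == pytest.approx(12.5, rel=1e-4)

    def test_unknown_site_rejected(self):
        with pytest.raises(ValidationError):
            satellite_positions("gamma", 10.0)

    def test_satellite_continuity_in_J(self):
        """Apparent splitting varies smoothly with J (no jumps)."""
        Js = np.linspace(0.0, 120.0, 121)
        s = [satellite_positions("ipso", J)["splitting"] for J in Js]
        # |d(splitting)/dJ| <= 1 everywhere, so 1 MHz steps change the
        # splitting by at most 1 MHz if the curve is continuous
        assert np.all(np.abs(np.diff(s)) <= 1.0)


class TestSimulateIsotropic:
    def test_multiplet_resolved_in_spectrum(self, monoradical_system):
        axis = np.linspace(-2.0, 2.0, 4001)
        ls = LineShape(gaussian_width=0.05, lorentzian_width=0.02)
        spec = simulate_isotropic(monoradical_system, axis, ls)
        ab = spec.absorption()
        peaks, _ = find_peaks(ab.intensity, prominence=0.02 * ab.intensity.max())
        assert len(peaks) == 7

    def test_satellites_appear_with_abundance(self):
        sys_ = make_pair(J=0.0)
        axis = np.linspace(-20.0, 20.0, 8001)
        ls = LineShape(gaussian_width=0.05, lorentzian_width=0.02)
        clean = simulate_isotropic(sys_, axis, ls, abundance=0.0)
        with_sat = simulate_isotropic(sys_, axis, ls, abundance=C13_ABUNDANCE)
        diff = with_sat.absorption().intensity - (
            clean.absorption().intensity * (1 - C13_ABUNDANCE) ** 36
        )
        # satellite intensity appears at a/2 offsets of each site
        for site, a in C13_HFCC.items():
            idx = np.argmin(np.abs(axis - a / 2.0))
            assert diff[idx] > 0

    def test_resolution_warning(self, monoradical_system):
        axis = np.linspace(-10.0, 10.0, 101)  # far too coarse
        ls = LineShape(gaussian_width=0.05)
        with pytest.warns(UserWarning, match="axis step"):
            simulate_isotropic(monoradical_system, axis, ls)

    def test_double_integral_positive(self, monoradical_system):
        axis = np.linspace(-3.0, 3.0, 4001)
        ls = LineShape(gaussian_width=0.05, lorentzian_width=0.02)
        spec = simulate_isotropic(monoradical_system, axis, ls)
        assert spec.derivative_order == 1
        assert spec.double_integral() > 0
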