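"""Seeded synthetic spectra emulating the five trityl model compounds.

The fixtures carry the published simulation parameters of the compound
series: a Finland-trityl monoradical (1a), two weakly coupled bis-trityls
with a ~3.5 nm bridge (2a methyl / 2b ethyl esters), the tris-trityl 3a
(three spins, equilateral geometry), and the short-bridged, exchange-
coupled bis-trityls 4a / 4b (J = 77 / 75 MHz, D = 7.0 MHz, 15% / 5%
monoradical impurity).  Hyperfine structure uses the localized per-centre
parameters — six alpha-protons of 0.3 MHz per methyl-ester trityl, four per
ethyl-ester trityl, and the aromatic 13C constants 31.25 / 25.00 / 6.20 /
8.40 MHz — so the strong-coupling halving of apparent couplings emerges
from diagonalization rather than being put in by hand.  (For 4b the
published APPARENT values, 8 equivalent nuclei of 0.13 MHz, are stored in
the truth record as printed and realized as four 0.26 MHz protons per
centre.)

The generator emulates X-band first-derivative cw detection with additive
white Gaussian noise scaled to the peak-to-peak signal and an optional
low-order polynomial baseline drift.  Noise and baseline are artifact
constructs of this package; real spectrometers add modulation distortion
and drift structure not modelled here.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .liquid import C13_ABUNDANCE, simulate_isotropic
from .powder import MixtureModel, PowderGrid, simulate_powder
from .spectrum import LineShape, Spectrum
from .systems import (
    ElectronSpin,
    HyperfineNucleus,
    PairCoupling,
    SpinSystem,
    ValidationError,
)

#: the compounds the generator knows
COMPOUNDS = ("1a", "2a", "2b", "3a", "4a", "4b")

G_ISO_DEFAULT = 2.0035  # mid-window of the published 2.00344-2.00351 range

#: small axial g-anisotropy used for frozen solution (mean = G_ISO_DEFAULT)
G_PRINCIPAL_FROZEN = (2.00345, 2.00345, 2.00360)

LIQUID_LINESHAPE = LineShape(gaussian_width=0.05, lorentzian_width=0.05)  # MHz
FROZEN_LINESHAPE = LineShape(gaussian_width=2.36, lorentzian_width=1.00)  # MHz

MW_FREQUENCY = 9.4  # GHz


@dataclass
class CompoundFixture:
    """Fully specified synthetic stand-in for one compound."""

    name: str
    system: SpinSystem  # liquid-solution spin system (isotropic)
    frozen_system: Optional[SpinSystem]  # frozen variant (protons unresolved)
    monoradical_system: Optional[SpinSystem]
    monoradical_fraction: float
    lineshape_liquid: LineShape
    lineshape_frozen: LineShape
    truth: dict = field(default_factory=dict)

    @property
    def frozen(self) -> bool:
        return self.frozen_system is not None

    @property
    def J(self) -> float:
        return self.system.couplings[0].J if self.system.couplings else 0.0

    @property
    def D(self) -> float:
        if self.frozen_system and self.frozen_system.couplings:
            return self.frozen_system.couplings[0].D
        return 0.0


def _electron(label: str, frozen: bool) -> ElectronSpin:
    return ElectronSpin(
        label=label,
        g_iso=G_ISO_DEFAULT,
        g_principal=G_PRINCIPAL_FROZEN if frozen else None,
    )


def _protons(n: int, a: float, electron: int) -> HyperfineNucleus:
    return HyperfineNucleus(
        isotope="1H", spin_quantum_number=0.5, a_iso=a, n_equivalent=n,
        attached_to=electron, site="alpha",
    )


_TRIANGLE_AXES = [
    (1.0, 0.0, 0.0),
    (np.cos(np.pi / 3), np.sin(np.pi / 3), 0.0),
    (np.cos(2 * np.pi / 3), np.sin(2 * np.pi / 3), 0.0),
]

# (n alpha-protons per centre, a_iso MHz per centre)
_PROTONS = {"1a": (6, 0.3), "2a": (6, 0.3), "2b": (4, 0.3), "3a": (6, 0.3),
            "4a": (6, 0.3), "4b": (4, 0.26)}
_J = {"4a": 77.0, "4b": 75.0}
_D = {"2a": 1.2, "2b": 1.2, "3a": 1.2, "4a": 7.0, "4b": 7.0}
_MONO_FRACTION = {"4a": 0.15, "4b": 0.05}


def make_fixture(name: str) -> CompoundFixture:
    """Build the fixture for one of the compounds ``1a 2a 2b 3a 4a 4b``."""
    if name not in COMPOUNDS:
        raise ValidationError(f"unknown compound {name!r}; valid fixtures: {COMPOUNDS}")

    n_h, a_h = _PROTONS[name]
    n_electrons = {"1a": 1, "3a": 3}.get(name, 2)
    J = _J.get(name, 0.0)
    D = _D.get(name, 0.0)
    frac = _MONO_FRACTION.get(name, 0.0)

    electrons = [_electron(f"trityl_{chr(65 + k)}", frozen=False) for k in range(n_electrons)]
    nuclei = [_protons(n_h, a_h, k) for k in range(n_electrons)]
    # liquid couplings carry exchange only: isotropic tumbling averages the
    # dipolar term to zero
    couplings = []
    if n_electrons == 2:
        couplings = [PairCoupling(spins=(0, 1), J=J, D=0.0)]
    elif n_electrons == 3:
        couplings = [
            PairCoupling(spins=pair, J=J, D=0.0, axis=_TRIANGLE_AXES[i])
            for i, pair in enumerate([(0, 1), (1, 2), (0, 2)])
        ]
    system = SpinSystem(electrons=electrons, nuclei=nuclei, couplings=couplings,
                        mw_frequency=MW_FREQUENCY)
    system.validate()

    # frozen variant: anisotropic g, dipolar coupling on, protons folded into
    # the 2.36 MHz Gaussian width
    frozen = copy.deepcopy(system)
    frozen.electrons = [_electron(e.label, frozen=True) for e in system.electrons]
    frozen.nuclei = []
    for c in frozen.couplings:
        c.D = D
        if c.axis is None:
            c.theta = np.pi / 2  # placeholder; powder averaging scans theta

    mono = None
    if n_electrons > 1:
        mono = SpinSystem(
            electrons=[_electron("mono", frozen=False)],
            nuclei=[_protons(n_h, a_h, 0)],
            couplings=[],
            mw_frequency=MW_FREQUENCY,
        )

    truth = {
        "name": name,
        "n_electrons": n_electrons,
        "g_iso": G_ISO_DEFAULT,
        "J_MHz": J,
        "D_MHz": D,
        "a_H_MHz": a_h,
        "n_protons_per_centre": n_h,
        "monoradical_fraction": frac,
        "gaussian_width_liquid_MHz": LIQUID_LINESHAPE.gaussian_width,
        "lorentzian_width_liquid_MHz": LIQUID_LINESHAPE.lorentzian_width,
        "gaussian_width_frozen_MHz": FROZEN_LINESHAPE.gaussian_width,
        "lorentzian_width_frozen_MHz": FROZEN_LINESHAPE.lorentzian_width,
    }
    if name == "4b":
        truth["apparent_a_H_MHz"] = 0.13
        truth["apparent_n_protons"] = 8
    if name == "4a":
        truth["apparent_a_H_MHz"] = 0.15
        truth["apparent_n_protons"] = 12

    return CompoundFixture(
        name=name,
        system=system,
        frozen_system=frozen,
        monoradical_system=mono,
        monoradical_fraction=frac,
        lineshape_liquid=LIQUID_LINESHAPE,
        lineshape_frozen=FROZEN_LINESHAPE,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# clean simulation shared by the generator and the spectrum fitter

def default_axis(mode: str) -> np.ndarray:
    if mode == "liquid":
        return np.linspace(-25.0, 25.0, 4096)
    return np.linspace(-25.0, 25.0, 2048)


def simulate_fixture(
    fixture: CompoundFixture,
    mode: str = "liquid",
    axis: Optional[np.ndarray] = None,
    overrides: Optional[Mapping[str, float]] = None,
    abundance: float = C13_ABUNDANCE,
    grid: Optional[PowderGrid] = None,
    derivative_order: int = 1,
) -> Spectrum:
    """Noise-free first-derivative spectrum of a fixture.

    ``overrides`` may replace any of ``J``, ``D``, ``a_H``,
    ``gaussian_width``, ``lorentzian_width``, ``monoradical_fraction``; the
    same code path serves generation and least-squares refitting, so a fit
    of a self-simulated spectrum can reach zero residual.  The monoradical
    impurity enters as a fraction of the integrated intensity.
    """
    ov = dict(overrides or {})
    if mode not in ("liquid", "frozen"):
        raise ValidationError(f"mode must be 'liquid' or 'frozen', got {mode!r}")
    if axis is None:
        axis = default_axis(mode)
    frac = float(ov.get("monoradical_fraction", fixture.monoradical_fraction))
    if not (0.0 <= frac <= 1.0):
        raise ValidationError("monoradical_fraction must lie in [0, 1]")

    if mode == "liquid":
        base = fixture.lineshape_liquid
        lineshape = LineShape(
            gaussian_width=float(ov.get("gaussian_width", base.gaussian_width)),
            lorentzian_width=float(ov.get("lorentzian_width", base.lorentzian_width)),
        )
        system = copy.deepcopy(fixture.system)
        for c in system.couplings:
            c.J = float(ov.get("J", c.J))
        if "a_H" in ov:
            for nuc in system.nuclei:
                if nuc.isotope == "1H":
                    nuc.a_iso = float(ov["a_H"])
        spec = simulate_isotropic(system, axis, lineshape,
                                  derivative_order=derivative_order,
                                  abundance=abundance)
        y = _unit_normalized(spec)
        if frac > 0 and fixture.monoradical_system is not None:
            mono = copy.deepcopy(fixture.monoradical_system)
            if "a_H" in ov:
                for nuc in mono.nuclei:
                    if nuc.isotope == "1H":
                        nuc.a_iso = float(ov["a_H"])
            mspec = simulate_isotropic(mono, axis, lineshape,
                                       derivative_order=derivative_order,
                                       abundance=abundance)
            y = (1.0 - frac) * y + frac * _unit_normalized(mspec)
        out = spec.copy_with(intensity=y)
    else:
        if fixture.frozen_system is None:
            raise ValidationError(f"fixture {fixture.name} has no frozen mode")
        base = fixture.lineshape_frozen
        lineshape = LineShape(
            gaussian_width=float(ov.get("gaussian_width", base.gaussian_width)),
            lorentzian_width=float(ov.get("lorentzian_width", base.lorentzian_width)),
        )
        system = copy.deepcopy(fixture.frozen_system)
        for c in system.couplings:
            c.J = float(ov.get("J", c.J))
            c.D = float(ov.get("D", c.D))
        grid = grid or PowderGrid(n_theta=256)
        components: list[tuple[SpinSystem, float]] = [(system, 1.0 - frac)]
        if frac > 0:
            mono_frozen = SpinSystem(
                electrons=[_electron("mono", frozen=True)],
                couplings=[],
                nuclei=[],
                mw_frequency=system.mw_frequency,
            )
            components.append((mono_frozen, frac))
        else:
            components = [(system, 1.0)]
        spec = simulate_powder(MixtureModel(components), grid, lineshape, axis,
                               derivative_order=derivative_order)
        out = spec.copy_with(intensity=_unit_normalized(spec))
    out.metadata.update({"compound": fixture.name, "mode": mode})
    return out


def _unit_normalized(spec: Spectrum) -> np.ndarray:
    """Scale to unit double integral (per-signal normalization)."""
    norm = spec.double_integral() if spec.derivative_order == 1 else spec.integral()
    if norm <= 0:
        return spec.intensity
    return spec.intensity / norm


#: illustrative J(T) anchors: room-temperature J and the value extrapolated to
#: the ~115 K glass transition.  These are synthetic reconstruction anchors
#: (the underlying per-temperature measurements are not tabulated anywhere),
#: so series built from them are for demonstration and self-tests only.
_JT_ANCHORS = {"4a": (77.0, 22.0), "4b": (75.0, 20.0)}
_JT_T_ANCHORS = (293.0, 115.0)


def make_temperature_series(
    name: str,
    temperatures: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
):
    """Synthetic linear J(T) series for the exchange-coupled compounds.

    The line passes through the room-temperature coupling and its
    glass-transition extrapolation; optional Gaussian noise (MHz) is added
    per point.  Clearly non-authoritative: a stand-in for unpublished
    per-temperature measurements.
    """
    from .fitting import TemperatureSeries

    if name not in _JT_ANCHORS:
        raise ValidationError(f"no temperature series for {name!r}; known: "
                              f"{sorted(_JT_ANCHORS)}")
    if temperatures is None:
        temperatures = np.arange(213.0, 294.0, 20.0)
    t_hi, t_lo = _JT_T_ANCHORS
    j_hi, j_lo = _JT_ANCHORS[name]
    slope = (j_hi - j_lo) / (t_hi - t_lo)
    intercept = j_hi - slope * t_hi
    J = slope * np.asarray(temperatures, dtype=float) + intercept
    if noise_sd > 0:
        J = J + np.random.default_rng(seed).normal(0.0, noise_sd, size=J.shape)
    return TemperatureSeries(points=list(zip(map(float, temperatures), map(float, J))))


def generate_spectrum(
    fixture: CompoundFixture,
    mode: str = "liquid",
    noise_sd: float = 0.0,
    baseline_order: int = 0,
    baseline_amplitude: float = 0.0,
    seed: Optional[int] = None,
    axis: Optional[np.ndarray] = None,
    grid: Optional[PowderGrid] = None,
) -> Spectrum:
    """Seeded noisy synthetic spectrum with the generating truth embedded.

    ``noise_sd`` is the white-noise standard deviation relative to the
    peak-to-peak signal amplitude (an SNR of 50 corresponds to
    ``noise_sd = 0.02``); ``baseline_amplitude`` scales a random polynomial
    drift of order ``baseline_order`` to the same reference.  Identical
    seeds give bit-identical traces.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    clean = simulate_fixture(fixture, mode=mode, axis=axis, grid=grid)
    y = clean.intensity.copy()
    ptp = float(y.max() - y.min())
    rng = np.random.default_rng(seed)
    if baseline_order > 0 and baseline_amplitude > 0:
        x = np.linspace(-1.0, 1.0, len(y))
        coeffs = rng.normal(0.0, baseline_amplitude * ptp, size=baseline_order + 1)
        y = y + np.polynomial.polynomial.polyval(x, coeffs)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * ptp, size=y.shape)
    out = clean.copy_with(intensity=y)
    out.metadata.update(
        {
            "truth": dict(fixture.truth),
            "noise_sd": noise_sd,
            "baseline_order": baseline_order,
            "baseline_amplitude": baseline_amplitude,
            "seed": seed,
        }
    )
    return out
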