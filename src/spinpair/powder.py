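"""Frozen-solution powder spectra: exchange-shifted Pake patterns.

In frozen solution the dipolar coupling d(theta) = D (1 - 3 cos^2 theta)
survives orientation averaging and produces the Pake pattern.  Its
singularities depend on the coupling regime:

* weak coupling (|J - D/2| / |delta_omega| <= 0.1): the two halves of the
  pattern are shifted against each other by the exchange coupling;
  nu_perp = |D +/- J| / 2 and nu_par = |-2D +/- J| / 2.
* strong coupling (ratio >= 10): an apparently undistorted Pake pattern
  stretched by 3/2, nu_perp = |1.5 D| / 2 and nu_par = |-3 D| / 2, so the
  singularities sit 50% higher than a weak-coupling pattern of the same D.
* intermediate: no closed form; the spectrum is obtained only by full
  diagonalization per orientation, which this module performs in all cases.

Orientation averaging is one-dimensional in cos(theta) (Gauss-Legendre) for
axial two-spin problems and a full spherical product grid when couplings
carry molecular-frame axes (the tris-radical with three dipolar tensors
tilted by 60 degrees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hamiltonian import (
    batched_transitions,
    dipolar_secular_coefficient,
    transitions,
    _two_spin_one_nucleus,
)
from .liquid import enumerate_configs
from .spectrum import LineShape, Spectrum, broaden
from .systems import MHZ_PER_MT, SpinSystem, ValidationError


class RegimeError(ValueError):
    """Raised when a closed form is requested outside its regime of validity."""


class ExtractionError(RuntimeError):
    """Raised when Pake singularities cannot be located in a spectrum."""


@dataclass
class PowderGrid:
    """Orientation quadrature for powder averaging.

    ``nodes`` holds cos(theta) values; ``weights`` the matching quadrature
    weights (summing to 1).  ``n_phi`` > 1 turns the grid into a spherical
    product grid with uniform azimuthal sampling, needed when inter-spin
    axes are fixed in the molecular frame.
    """

    n_theta: int = 256
    n_phi: int = 1
    scheme: str = "gauss-legendre"
    nodes: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_theta < 2:
            raise ValidationError("n_theta must be >= 2")
        # integrate over cos(theta) in [0, 1]; d(theta) is symmetric under inversion
        x, w = np.polynomial.legendre.leggauss(self.n_theta)
        self.nodes = 0.5 * (x + 1.0)
        self.weights = w / w.sum()

    def orientations(self) -> tuple[np.ndarray, np.ndarray]:
        """Field directions (unit vectors) and weights on the (hemi)sphere."""
        cos_t = self.nodes
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
        if self.n_phi <= 1:
            dirs = np.column_stack([sin_t, np.zeros_like(sin_t), cos_t])
            return dirs, self.weights
        phi = (np.arange(self.n_phi) + 0.5) * 2.0 * np.pi / self.n_phi
        dirs = []
        wts = []
        for ct, st, w in zip(cos_t, sin_t, self.weights):
            for p in phi:
                dirs.append([st * np.cos(p), st * np.sin(p), ct])
                wts.append(w / self.n_phi)
        return np.asarray(dirs), np.asarray(wts)


@dataclass
class MixtureModel:
    """Fraction-weighted mixture of spin systems (biradical + monoradical)."""

    components: list[tuple[SpinSystem, float]]

    def validate(self) -> None:
        if not self.components:
            raise ValidationError("mixture needs at least one component")
        fracs = np.array([f for _, f in self.components], dtype=float)
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {fracs.sum()}, not 1")
        for s, _ in self.components:
            s.validate()


# ---------------------------------------------------------------------------

def dipolar_splitting(
    theta: float,
    D: float,
    J: float = 0.0,
    regime: str = "weak",
    delta_omega: Optional[float] = None,
) -> np.ndarray:
    """Frequency offsets (MHz) of the dipolar doublet at one orientation.

    ``regime='weak'`` and ``'strong'`` evaluate the closed forms in terms of
    d(theta) = D (1 - 3 cos^2 theta): weak gives the doublet offset
    |d + J| / 2 (J signed, so exchange adds to or subtracts from the
    dipolar shift), strong gives |1.5 d| / 2.  ``regime='full'``
    diagonalizes the two-spin Hamiltonian with resonance-frequency
    difference ``delta_omega`` and returns the exact offsets of each spin's
    transitions from its own resonance; it converges to the weak closed
    form for delta_omega >> |J|, |D| and to the strong form for
    delta_omega -> 0.  There is no closed form for the intermediate regime.
    """
    d = dipolar_secular_coefficient(D, theta)
    if regime == "weak":
        return np.array([abs(d + J) / 2.0])
    if regime == "strong":
        return np.array([abs(1.5 * d) / 2.0])
    if regime == "intermediate":
        raise RegimeError(
            "no closed form exists in the intermediate regime; the spectrum "
            "can only be obtained by diagonalization of the complete spin "
            "Hamiltonian (use regime='full' with an explicit delta_omega)"
        )
    if regime != "full":
        raise ValidationError(f"unknown regime {regime!r}")
    if delta_omega is None:
        raise ValidationError("regime='full' requires delta_omega")

    system = _two_spin_one_nucleus(2.0 * abs(delta_omega), 0.0, 9.4)
    system.couplings[0].J = J
    B0 = system.center_field_mT()
    nu0 = MHZ_PER_MT * system.electrons[0].g_iso * B0
    key = (0, 1)
    ts = transitions(system, B0, (0.5,), d_override={key: d})
    nu1 = nu0 + abs(delta_omega)  # electron carrying the shift
    nu2 = nu0
    centres = np.array([nu1, nu2])
    offsets = []
    for f in ts.frequencies:
        offsets.append(abs(f - centres[np.argmin(np.abs(f - centres))]))
    out = np.unique(np.round(np.sort(offsets), 9))
    return out


def powder_sticks(
    system: SpinSystem,
    grid: PowderGrid,
    reference_g: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation- and configuration-summed stick list of one component.

    Offsets are in MHz about the resonance of ``reference_g`` (default: the
    component's own mean g) at the component's microwave frequency.  For
    couplings carrying a molecular-frame ``axis`` the effective angle per
    orientation is the angle between that axis and the field direction;
    couplings without an axis use the polar angle directly.  Axial
    g-anisotropy (from ``g_principal``) enters through the effective
    g-value g(theta)^2 = g_par^2 cos^2 + g_perp^2 sin^2 of each electron,
    with the g-frame z-axis along the molecular z-axis.
    """
    system.validate()
    if reference_g is None:
        reference_g = float(np.mean([e.g_iso for e in system.electrons]))
    B0 = 1e3 * system.mw_frequency / (MHZ_PER_MT * reference_g)
    nu_ref = MHZ_PER_MT * reference_g * B0

    needs_sphere = any(c.axis is not None for c in system.couplings)
    if needs_sphere and grid.n_phi <= 1:
        grid = PowderGrid(n_theta=grid.n_theta, n_phi=2 * grid.n_theta)
    dirs, wts = grid.orientations()

    configs, probs = enumerate_configs(system)

    def g_eff(e, ct2: float) -> float:
        if e.g_principal is None:
            return e.g_iso
        gx, gy, gz = e.g_principal
        g_perp2 = ((gx + gy) / 2.0) ** 2
        return float(np.sqrt(gz**2 * ct2 + g_perp2 * (1.0 - ct2)))

    all_pos: list[np.ndarray] = []
    all_wt: list[np.ndarray] = []
    for direction, w_or in zip(dirs, wts):
        ct2 = direction[2] ** 2
        d_over = {}
        for c in system.couplings:
            if c.axis is not None:
                cos_ang = float(np.dot(direction, np.asarray(c.axis)))
            else:
                cos_ang = direction[2]
            d_over[tuple(sorted(c.spins))] = c.D * (1.0 - 3.0 * cos_ang**2)
        gs = [g_eff(e, ct2) for e in system.electrons]
        ts = batched_transitions(system, B0, configs, probs, d_override=d_over, g_values=gs)
        all_pos.append(ts.frequencies - nu_ref)
        all_wt.append(ts.intensities * w_or)
    return np.concatenate(all_pos), np.concatenate(all_wt)


def simulate_powder(
    mixture: MixtureModel | SpinSystem,
    grid: PowderGrid,
    lineshape: LineShape,
    axis: np.ndarray,
    derivative_order: int = 1,
) -> Spectrum:
    """Simulate the frozen-solution spectrum of a (possibly mixed) sample.

    Each component is powder-averaged by full diagonalization per
    orientation; monoradical components contribute unsplit lines scaled by
    their fraction, and the mixture spectrum is exactly the fraction-
    weighted sum of the component spectra.
    """
    if isinstance(mixture, SpinSystem):
        mixture = MixtureModel([(mixture, 1.0)])
    mixture.validate()
    axis = np.asarray(axis, dtype=float)
    ref_g = float(np.mean([e.g_iso for e in mixture.components[0][0].electrons]))

    pos_all: list[np.ndarray] = []
    wt_all: list[np.ndarray] = []
    for system, fraction in mixture.components:
        if fraction == 0:
            continue
        pos, wt = powder_sticks(system, grid, reference_g=ref_g)
        # normalize per spin so a fraction is a molecular fraction, not a
        # transition-count fraction
        total = wt.sum()
        if total > 0:
            wt = wt / total
        pos_all.append(pos)
        wt_all.append(wt * fraction)
    y = broaden(axis, np.concatenate(pos_all), np.concatenate(wt_all), lineshape, derivative_order)
    mw = mixture.components[0][0].mw_frequency
    return Spectrum(
        axis=axis,
        intensity=y,
        axis_unit="MHz",
        derivative_order=derivative_order,
        mw_frequency=mw,
        metadata={"kind": "powder", "n_theta": grid.n_theta, "n_phi": grid.n_phi},
    )


def pake_singularities(
    spectrum: Spectrum,
    center: Optional[float] = None,
    min_prominence: float = 0.02,
) -> tuple[float, float]:
    """Locate the Pake singularities of an absorption-mode powder spectrum.

    Returns ``(nu_perp, nu_par)`` as positive offsets from ``center``
    (default: the axis midpoint).  ``nu_perp`` comes from the dominant
    maxima pair flanking the centre; ``nu_par`` from the outer shoulders,
    located at the steepest descent beyond each maximum.  Raises
    :class:`ExtractionError` when the turning points are not resolved.
    """
    from scipy.signal import find_peaks

    spec = spectrum.absorption() if spectrum.derivative_order == 1 else spectrum
    x, y = spec.axis, spec.intensity
    if center is None:
        center = 0.5 * (x[0] + x[-1])
    peaks, props = find_peaks(y, prominence=min_prominence * y.max())
    left = [p for p in peaks if x[p] < center]
    right = [p for p in peaks if x[p] >= center]
    if not left or not right:
        raise ExtractionError(
            "could not resolve a singularity pair flanking the centre "
            "(line width or noise too large)"
        )
    pl = max(left, key=lambda p: y[p])
    pr = max(right, key=lambda p: y[p])
    nu_perp = 0.5 * (_refine_peak(x, y, pr) - _refine_peak(x, y, pl))

    # outer shoulders: the outermost steep-descent feature on each wing.
    # The parallel edge is a step, so |dy| has a local extremum there that is
    # well separated from the much larger flank extremum next to the maximum.
    from scipy.signal import savgol_filter

    # smooth at the scale of the resolved singularity (whose width reflects
    # the broadening kernel) so the shoulder step stays above slope noise
    from scipy.signal import peak_widths

    fwhm_pts = float(peak_widths(y, [pr], rel_height=0.5)[0][0])
    win = int(2 * max(2, round(1.5 * fwhm_pts)) + 1)
    dy = np.gradient(savgol_filter(y, min(win, len(y) // 2 * 2 - 1), 2), x)
    # spurious noise slopes are rejected against the slope noise level
    # estimated from the outermost 5% of each wing
    edge = max(4, len(y) // 20)
    noise_dy = 1.4826 * float(np.median(np.abs(np.concatenate([dy[:edge], dy[-edge:]]))))
    h_r = max(0.03 * (-dy[pr:]).max(), 4.0 * noise_dy)
    h_l = max(0.03 * dy[: pl + 1].max(), 4.0 * noise_dy)
    right_min, rprops = find_peaks(-dy[pr:], height=h_r)
    left_max, lprops = find_peaks(dy[: pl + 1], height=h_l)
    # exclude the peak's own flank, then take the strongest remaining feature
    guard = 2.0 * fwhm_pts
    keep_r = right_min >= guard
    keep_l = left_max <= pl - guard
    if not keep_r.any() or not keep_l.any():
        raise ExtractionError("outer shoulders not detectable on the wings")
    r_idx = right_min[keep_r]
    i_r = pr + int(r_idx[np.argmax(rprops["peak_heights"][keep_r])])
    l_idx = left_max[keep_l]
    i_l = int(l_idx[np.argmax(lprops["peak_heights"][keep_l])])
    nu_par = 0.5 * (x[i_r] - x[i_l])
    if nu_par <= nu_perp:
        warnings.warn("outer shoulders not resolved beyond the perpendicular maxima",
                      stacklevel=2)
    return float(nu_perp), float(nu_par)


def _refine_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid peak position by parabolic interpolation through 3 points."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[i] + np.clip(delta, -1, 1) * (x[i + 1] - x[i]))
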