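"""Spectrum container, Gaussian/Lorentzian lineshapes and two-column ASCII I/O.

Line widths are peak-to-peak widths of the first-derivative line, the
quantity read off a cw EPR spectrum: for a Gaussian of standard deviation
sigma the peak-to-peak width is 2 sigma; for a Lorentzian of half-width
gamma it is 2 gamma / sqrt(3).  Mixed shapes are produced by convolving the
two kernels (a Voigt profile).

The on-disk format is two columns (axis, intensity) with '#'-prefixed
``key: value`` header lines carrying at least ``axis_unit``,
``mw_frequency_GHz`` and ``derivative_order``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .systems import ValidationError


class SpectrumFormatError(ValueError):
    """Raised on malformed spectrum files, carrying the offending line number."""


@dataclass
class LineShape:
    """Voigt-by-convolution lineshape given as peak-to-peak widths."""

    gaussian_width: float = 0.0  # peak-to-peak, same unit as the axis
    lorentzian_width: float = 0.0
    kind: str = "voigt"

    def validate(self) -> None:
        if self.gaussian_width < 0 or self.lorentzian_width < 0:
            raise ValidationError("line widths must be >= 0")
        if self.gaussian_width == 0 and self.lorentzian_width == 0:
            raise ValidationError("at least one line width must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation."""
        return self.gaussian_width / 2.0

    @property
    def gamma(self) -> float:
        """Lorentzian half-width at half-maximum."""
        return np.sqrt(3.0) / 2.0 * self.lorentzian_width

    @property
    def narrowest(self) -> float:
        widths = [w for w in (self.gaussian_width, self.lorentzian_width) if w > 0]
        return min(widths)


@dataclass
class Spectrum:
    """Field- or frequency-swept intensity trace."""

    axis: np.ndarray
    intensity: np.ndarray
    axis_unit: str = "MHz"  # "MHz" or "mT"
    derivative_order: int = 1
    mw_frequency: float = 9.4  # GHz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.axis.shape != self.intensity.shape:
            raise ValidationError("axis and intensity must be 1-D arrays of equal length")
        if len(self.axis) < 2:
            raise ValidationError("a spectrum needs at least two points")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("axis must be strictly monotone")

    @property
    def step(self) -> float:
        return float(abs(self.axis[1] - self.axis[0]))

    def copy_with(self, **kwargs) -> "Spectrum":
        d = dict(
            axis=self.axis.copy(),
            intensity=self.intensity.copy(),
            axis_unit=self.axis_unit,
            derivative_order=self.derivative_order,
            mw_frequency=self.mw_frequency,
            metadata=dict(self.metadata),
        )
        d.update(kwargs)
        return Spectrum(**d)

    def integral(self) -> float:
        """Area under the trace (trapezoid)."""
        return float(np.trapezoid(self.intensity, self.axis))

    def absorption(self) -> "Spectrum":
        """Integrate a first-derivative trace once to recover absorption."""
        if self.derivative_order == 0:
            return self
        from scipy.integrate import cumulative_trapezoid

        absorb = cumulative_trapezoid(self.intensity, self.axis, initial=0.0)
        return self.copy_with(intensity=absorb, derivative_order=self.derivative_order - 1)

    def double_integral(self) -> float:
        """Second integral of a first-derivative spectrum: the spin count proxy."""
        return self.absorption().integral()


# ---------------------------------------------------------------------------
# lineshape kernels and stick-spectrum convolution

def gaussian_kernel(step: float, sigma: float, span_sigmas: float = 8.0) -> np.ndarray:
    """Unit-area Gaussian kernel sampled on the spectrum grid."""
    half = max(1, int(np.ceil(span_sigmas * sigma / step)))
    x = np.arange(-half, half + 1) * step
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / (k.sum() * step)


def lorentzian_kernel(step: float, gamma: float, span_gammas: float = 400.0) -> np.ndarray:
    """Unit-area (numerically renormalized) Lorentzian kernel on the grid."""
    half = max(1, int(np.ceil(span_gammas * gamma / step)))
    x = np.arange(-half, half + 1) * step
    k = gamma / np.pi / (x**2 + gamma**2)
    return k / (k.sum() * step)


def broaden(
    axis: np.ndarray,
    sticks_pos: np.ndarray,
    sticks_weight: np.ndarray,
    lineshape: LineShape,
    derivative_order: int = 1,
) -> np.ndarray:
    """Accumulate stick transitions on a grid and convolve with the lineshape.

    Sticks are deposited with linear (area-preserving) interpolation between
    the two neighbouring grid points; sticks outside the axis are ignored.
    Returns the absorption trace, differentiated ``derivative_order`` times.
    """
    lineshape.validate()
    axis = np.asarray(axis, dtype=float)
    step = axis[1] - axis[0]
    y = np.zeros_like(axis)
    pos = np.asarray(sticks_pos, dtype=float)
    wts = np.asarray(sticks_weight, dtype=float)
    inside = (pos >= axis[0]) & (pos <= axis[-1])
    pos, wts = pos[inside], wts[inside]
    frac = (pos - axis[0]) / step
    lo = np.floor(frac).astype(int)
    hi = np.minimum(lo + 1, len(axis) - 1)
    t = frac - lo
    np.add.at(y, lo, wts * (1.0 - t) / step)
    np.add.at(y, hi, wts * t / step)

    from scipy.signal import fftconvolve

    if lineshape.gaussian_width > 0:
        y = fftconvolve(y, gaussian_kernel(step, lineshape.sigma), mode="same") * step
    if lineshape.lorentzian_width > 0:
        y = fftconvolve(y, lorentzian_kernel(step, lineshape.gamma), mode="same") * step
    for _ in range(derivative_order):
        y = np.gradient(y, step)
    return y


# ---------------------------------------------------------------------------
# file I/O

_REQUIRED_HEADERS = ("axis_unit", "mw_frequency_GHz", "derivative_order")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as headered two-column ASCII (12 significant digits)."""
    lines = [
        f"# axis_unit: {spectrum.axis_unit}",
        f"# mw_frequency_GHz: {spectrum.mw_frequency:.12g}",
        f"# derivative_order: {spectrum.derivative_order}",
    ]
    if spectrum.metadata:
        lines.append(f"# metadata: {json.dumps(spectrum.metadata, sort_keys=True)}")
    for x, y in zip(spectrum.axis, spectrum.intensity):
        lines.append(f"{x:.12g} {y:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a headered two-column ASCII spectrum; inverse of write_spectrum."""
    headers: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                headers[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpectrumFormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric value") from exc
        if len(xs) >= 2 and (xs[-1] - xs[-2]) * (xs[1] - xs[0]) <= 0:
            raise SpectrumFormatError(f"{path}:{lineno}: axis not strictly monotone")
    missing = [h for h in _REQUIRED_HEADERS if h not in headers]
    if missing:
        raise SpectrumFormatError(f"{path}: missing header keys {missing}")
    metadata = json.loads(headers["metadata"]) if "metadata" in headers else {}
    return Spectrum(
        axis=np.array(xs),
        intensity=np.array(ys),
        axis_unit=headers["axis_unit"],
        derivative_order=int(headers["derivative_order"]),
        mw_frequency=float(headers["mw_frequency_GHz"]),
        metadata=metadata,
    )
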