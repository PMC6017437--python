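"""Regime-correct conversion between dipolar coupling D and distance r.

The point-dipole relation for a weakly coupled electron pair is

    D = 52.01 MHz nm^3 / r^3.

In the strong-coupling regime the powder singularities sit 50% higher in
frequency than a weak-coupling pattern of the same distance, so the
apparent coupling constant read off the spectrum is stretched by 3/2:

    D_strong = 1.5 * 52.01 MHz nm^3 / r^3.

Applying the weak-coupling formula to a strong-coupling pattern therefore
biases distances to 1.5^(-1/3) ~ 87% of their true value.  No closed form
exists in the intermediate regime; there, only full spectral simulation
relates D to r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .systems import ValidationError

#: point-dipole constant for two g ~ 2.0035 electrons, MHz nm^3
DIPOLAR_CONSTANT = 52.01

#: stretch of the apparent dipolar coupling in the strong-coupling regime
STRONG_STRETCH = 1.5

# mu0/(4 pi) * muB^2 / h in MHz nm^3 (for the opt-in g-dependent constant)
_MU0_MUB2_OVER_H = 12.9801


class RegimeError(ValueError):
    """Raised for distance conversion requests in the intermediate regime."""


@dataclass
class DistanceResult:
    """Outcome of a D <-> r conversion."""

    r: float  # nm
    D: float  # MHz
    regime: str
    formula: str
    bias_note: Optional[str] = None


def dipolar_constant(g1: float = 2.0035, g2: float = 2.0035) -> float:
    """g-dependent point-dipole constant mu0 muB^2 g1 g2 / (4 pi h), MHz nm^3."""
    return _MU0_MUB2_OVER_H * g1 * g2


def _check_regime(regime: str) -> float:
    if regime == "weak":
        return 1.0
    if regime == "strong":
        return STRONG_STRETCH
    if regime == "intermediate":
        raise RegimeError(
            "no closed-form distance conversion exists in the intermediate "
            "regime; simulate the full spectrum instead"
        )
    raise ValidationError(f"unknown regime {regime!r} (use 'weak' or 'strong')")


def distance_from_D(D: float, regime: str = "weak", constant: float = DIPOLAR_CONSTANT) -> DistanceResult:
    """Inter-spin distance (nm) from a dipolar coupling constant (MHz)."""
    stretch = _check_regime(regime)
    if not D > 0:
        raise ValidationError(f"D must be positive, got {D}")
    r = (stretch * constant / D) ** (1.0 / 3.0)
    note = None
    if regime == "strong":
        note = (
            "weak-formula misread of this pattern would give "
            f"{r * STRONG_STRETCH ** (-1.0 / 3.0):.4g} nm "
            f"({100 * STRONG_STRETCH ** (-1.0 / 3.0):.1f}% of actual)"
        )
    formula = "D = 1.5 * 52.01/r^3" if regime == "strong" else "D = 52.01/r^3"
    return DistanceResult(r=float(r), D=float(D), regime=regime, formula=formula, bias_note=note)


def D_from_distance(r: float, regime: str = "weak", constant: float = DIPOLAR_CONSTANT) -> float:
    """Dipolar coupling constant (MHz) from an inter-spin distance (nm)."""
    stretch = _check_regime(regime)
    if not r > 0:
        raise ValidationError(f"r must be positive, got {r}")
    return stretch * constant / r**3


def apparent_distance_bias() -> float:
    """Ratio apparent/actual distance when the weak formula is misapplied.

    A Pake pattern stretched by 3/2 read with the weak-coupling formula
    yields distances at 1.5^(-1/3) ~ 0.874 of the actual separation.
    """
    return STRONG_STRETCH ** (-1.0 / 3.0)
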