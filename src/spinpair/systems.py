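"""Spin-system parameter containers and their config-file round trip.

A :class:`SpinSystem` is the parameter set of the high-field spin
Hamiltonian: up to three S = 1/2 electrons (isotropic or axial/rhombic
g-values), any number of groups of equivalent nuclei coupled isotropically
to one electron, and pairwise electron–electron couplings (isotropic
exchange J and dipolar coupling D with a geometry).

All couplings and hyperfine constants are stored in MHz; magnetic fields in
mT; the microwave frequency in GHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

#: Bohr magneton over Planck constant, MHz per mT (nu = MHZ_PER_MT * g * B).
MHZ_PER_MT = 13.9962

#: Electron resonance-frequency window accepted by default for organic radicals.
G_WINDOW = (1.9, 2.1)


class ValidationError(ValueError):
    """Raised when a spin-system parameter violates its physical bounds."""


class UnsupportedSystemError(ValueError):
    """Raised for system sizes outside the supported 1-3 electron range."""


@dataclass
class ElectronSpin:
    """One S = 1/2 electron spin centre.

    Parameters
    ----------
    label:
        Free-form identifier (e.g. ``"trityl_A"``).
    g_iso:
        Isotropic g-value.
    g_principal:
        Optional principal g-values ``(gx, gy, gz)`` for frozen-solution
        anisotropy; their mean must equal ``g_iso`` to 1e-6.
    """

    label: str = "e"
    g_iso: float = 2.0035
    g_principal: Optional[tuple[float, float, float]] = None

    def validate(self, g_window: tuple[float, float] = G_WINDOW) -> None:
        if not np.isfinite(self.g_iso):
            raise ValidationError(f"non-finite g_iso for electron {self.label!r}")
        if not (g_window[0] <= self.g_iso <= g_window[1]):
            raise ValidationError(
                f"g_iso={self.g_iso} outside {g_window} for electron {self.label!r}"
            )
        if self.g_principal is not None:
            gp = np.asarray(self.g_principal, dtype=float)
            if gp.shape != (3,):
                raise ValidationError("g_principal must have three components")
            if abs(gp.mean() - self.g_iso) > 1e-6:
                raise ValidationError(
                    f"mean of g_principal {gp.mean():.7f} != g_iso {self.g_iso:.7f}"
                )


@dataclass
class HyperfineNucleus:
    """A group of equivalent nuclei coupled isotropically to one electron."""

    isotope: str = "1H"
    spin_quantum_number: float = 0.5
    a_iso: float = 0.0  # MHz
    n_equivalent: int = 1
    attached_to: int = 0
    site: Optional[str] = None  # ipso/ortho/meta/para/alpha
    natural_abundance: float = 1.0

    def validate(self, n_electrons: int) -> None:
        if not np.isfinite(self.a_iso):
            raise ValidationError(f"non-finite a_iso for nucleus {self.isotope}")
        if self.n_equivalent < 1:
            raise ValidationError("n_equivalent must be >= 1")
        if not (0 <= self.attached_to < n_electrons):
            raise ValidationError(
                f"attached_to={self.attached_to} does not index an electron"
            )
        twice = 2 * self.spin_quantum_number
        if twice <= 0 or abs(twice - round(twice)) > 1e-12:
            raise ValidationError("spin_quantum_number must be a positive half-integer")
        if not (0.0 <= self.natural_abundance <= 1.0):
            raise ValidationError("natural_abundance must lie in [0, 1]")

    @property
    def projections(self) -> np.ndarray:
        """Allowed projections m_I of a single nucleus of this species."""
        i = self.spin_quantum_number
        return np.arange(-i, i + 1e-9, 1.0)


@dataclass
class PairCoupling:
    """Exchange + dipolar coupling between two electrons.

    ``J`` follows the convention that J > 0 couples the spins
    antiferromagnetically (singlet ground state).  ``D`` is the dipolar
    coupling constant of the point-dipole model; its angular factor is
    ``(1 - 3 cos^2 theta)`` with ``theta`` the angle between the inter-spin
    vector and the external field.  For powder work an ``axis`` unit vector
    in the molecular frame replaces the single angle.
    """

    spins: tuple[int, int] = (0, 1)
    J: float = 0.0  # MHz
    D: float = 0.0  # MHz
    theta: float = 0.0  # rad
    axis: Optional[tuple[float, float, float]] = None

    def validate(self, n_electrons: int) -> None:
        i, j = self.spins
        if i == j or not (0 <= i < n_electrons) or not (0 <= j < n_electrons):
            raise ValidationError(f"coupling spins {self.spins} invalid")
        if not (np.isfinite(self.J) and np.isfinite(self.D)):
            raise ValidationError("non-finite J or D")
        if self.D < 0:
            raise ValidationError("D must be >= 0 (sign carried by the angular factor)")
        if not (0.0 <= self.theta <= np.pi):
            raise ValidationError("theta must lie in [0, pi]")
        if self.axis is not None:
            ax = np.asarray(self.axis, dtype=float)
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValidationError("axis must be a unit vector")


@dataclass
class SpinSystem:
    """Complete parameter set of the spin Hamiltonian."""

    electrons: list[ElectronSpin] = field(default_factory=lambda: [ElectronSpin()])
    nuclei: list[HyperfineNucleus] = field(default_factory=list)
    couplings: list[PairCoupling] = field(default_factory=list)
    mw_frequency: float = 9.4  # GHz

    def validate(self) -> None:
        n = len(self.electrons)
        if n < 1:
            raise ValidationError("at least one electron is required")
        if n > 3:
            raise UnsupportedSystemError(f"{n} electrons unsupported (max 3)")
        for e in self.electrons:
            e.validate()
        for nuc in self.nuclei:
            nuc.validate(n)
        seen = set()
        for c in self.couplings:
            c.validate(n)
            key = tuple(sorted(c.spins))
            if key in seen:
                raise ValidationError(f"duplicate coupling for pair {key}")
            seen.add(key)
        if not np.isfinite(self.mw_frequency) or self.mw_frequency <= 0:
            raise ValidationError("mw_frequency must be positive and finite")

    @property
    def n_electrons(self) -> int:
        return len(self.electrons)

    def center_field_mT(self) -> float:
        """Resonance field of the mean g-value at the microwave frequency."""
        g = float(np.mean([e.g_iso for e in self.electrons]))
        return 1e3 * self.mw_frequency / (MHZ_PER_MT * g)

    def replace(self, **kwargs) -> "SpinSystem":
        import copy

        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            setattr(new, k, v)
        return new

    # ---- config round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["electrons"] = [asdict(e) for e in self.electrons]
        d["nuclei"] = [asdict(nu) for nu in self.nuclei]
        d["couplings"] = [asdict(c) for c in self.couplings]
        for c in d["couplings"]:
            c["spins"] = list(c["spins"])
            if c["axis"] is not None:
                c["axis"] = list(c["axis"])
        for e in d["electrons"]:
            if e["g_principal"] is not None:
                e["g_principal"] = list(e["g_principal"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        electrons = [
            ElectronSpin(
                label=e.get("label", "e"),
                g_iso=float(e.get("g_iso", 2.0035)),
                g_principal=tuple(e["g_principal"]) if e.get("g_principal") else None,
            )
            for e in d.get("electrons", [{}])
        ]
        nuclei = [
            HyperfineNucleus(
                isotope=nu.get("isotope", "1H"),
                spin_quantum_number=float(nu.get("spin_quantum_number", 0.5)),
                a_iso=float(nu.get("a_iso", 0.0)),
                n_equivalent=int(nu.get("n_equivalent", 1)),
                attached_to=int(nu.get("attached_to", 0)),
                site=nu.get("site"),
                natural_abundance=float(nu.get("natural_abundance", 1.0)),
            )
            for nu in d.get("nuclei", [])
        ]
        couplings = [
            PairCoupling(
                spins=tuple(c.get("spins", (0, 1))),
                J=float(c.get("J", 0.0)),
                D=float(c.get("D", 0.0)),
                theta=float(c.get("theta", 0.0)),
                axis=tuple(c["axis"]) if c.get("axis") else None,
            )
            for c in d.get("couplings", [])
        ]
        sys_ = cls(
            electrons=electrons,
            nuclei=nuclei,
            couplings=couplings,
            mw_frequency=float(d.get("mw_frequency", 9.4)),
        )
        sys_.validate()
        return sys_


def save_system(system: SpinSystem, path: str | Path) -> None:
    """Write a spin system to a YAML config file."""
    system.validate()
    Path(path).write_text(yaml.safe_dump(system.to_dict(), sort_keys=False))


def load_system(path: str | Path) -> SpinSystem:
    """Read a spin system from a YAML config file (inverse of save_system)."""
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValidationError(f"config {path} does not contain a mapping")
    return SpinSystem.from_dict(d)
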