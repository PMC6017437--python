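"""Room-temperature isotropic cw spectra: multiplets and 13C satellites.

A liquid-solution trityl spectrum consists of a narrow central line with
resolved alpha-proton structure, flanked by weak satellite lines from the
1.07%-abundant 13C isotopomers of the aromatic carbons.  For exchange-
coupled biradicals the satellite positions depend on the ratio of J to the
13C hyperfine coupling and interpolate between the full doublet (J = 0) and
the half-split doublet (|J| >> a); the central multiplet shows the
apparent-coupling halving and doubled multiplicity of the strongly coupled
spin pair automatically, because every nuclear configuration is treated by
exact diagonalization.

Simulation is carried out natively on a frequency-offset axis about the
mean-g resonance; trityl spectra span only ~2 G, so the first-order
field/frequency conversion applies across the sweep.
"""

from __future__ import annotations

import copy
import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .hamiltonian import batched_transitions, effective_satellite_splitting
from .spectrum import LineShape, Spectrum, broaden
from .systems import (
    MHZ_PER_MT,
    HyperfineNucleus,
    SpinSystem,
    ValidationError,
)

#: isotropic 13C hyperfine coupling constants of the aromatic sites, MHz
C13_HFCC: dict[str, float] = {"ipso": 31.25, "ortho": 25.00, "meta": 6.20, "para": 8.40}

#: equivalent aromatic carbons per site in a single trityl (three aryl rings)
SITE_CARBONS: dict[str, int] = {"ipso": 3, "ortho": 6, "meta": 6, "para": 3}

#: natural abundance of 13C
C13_ABUNDANCE = 0.0107

#: isotopomer components lighter than this are dropped from the expansion
WEIGHT_FLOOR = 1e-6


@dataclass
class IsotopomerComponent:
    """One isotopologue of the spin system with its statistical weight."""

    system_variant: SpinSystem
    weight: float
    site: Optional[str] = None  # None for the all-12C component


def group_projections(nucleus: HyperfineNucleus) -> tuple[np.ndarray, np.ndarray]:
    """Total projections and probabilities of a group of equivalent nuclei.

    For n equivalent spin-I nuclei the total projection M runs from -nI to
    +nI; the probability of each M is the multinomial degeneracy divided by
    (2I+1)^n (binomial weights for I = 1/2).
    """
    n_levels = int(round(2 * nucleus.spin_quantum_number + 1))
    counts = np.ones(n_levels)
    for _ in range(nucleus.n_equivalent - 1):
        counts = np.convolve(counts, np.ones(n_levels))
    probs = counts / counts.sum()
    i = nucleus.spin_quantum_number
    n = nucleus.n_equivalent
    ms = np.linspace(-n * i, n * i, len(counts))
    return ms, probs


def isotopomer_expansion(
    system: SpinSystem,
    site_carbon_counts: Optional[Mapping[str, int]] = None,
    abundance: float = C13_ABUNDANCE,
    hfcc_table: Optional[Mapping[str, float]] = None,
    weight_floor: float = WEIGHT_FLOOR,
) -> list[IsotopomerComponent]:
    """Expand a system into its all-12C and single-13C isotopomer components.

    Each trityl unit (one per electron) carries ``site_carbon_counts``
    equivalent aromatic carbons per site.  With abundance p and N carbons in
    total, the all-12C weight is (1-p)^N and a single substitution at a site
    with n equivalent carbons (summed over trityls) carries weight
    n p (1-p)^(N-1).  Multi-13C isotopomers are discarded; the discarded
    remainder is recorded in each component count so that weights plus
    remainder close to 1.  The single 13C is placed on the first electron;
    equivalent placements on the other trityls are covered by the weight.
    """
    if not (0.0 <= abundance <= 0.05):
        raise ValidationError("abundance must lie in [0, 0.05]")
    counts = dict(site_carbon_counts or SITE_CARBONS)
    hfccs = dict(hfcc_table or C13_HFCC)
    if any(c <= 0 for c in counts.values()):
        raise ValidationError("site carbon counts must be positive")
    unknown = set(counts) - set(hfccs)
    if unknown:
        raise ValidationError(f"no 13C hyperfine constant for sites {sorted(unknown)}")

    n_trityl = system.n_electrons
    N = n_trityl * sum(counts.values())
    p = abundance
    components = [IsotopomerComponent(system, (1.0 - p) ** N, site=None)]
    if p > 0:
        for site, n_per_trityl in counts.items():
            w = n_trityl * n_per_trityl * p * (1.0 - p) ** (N - 1)
            if w < weight_floor:
                continue
            variant = copy.deepcopy(system)
            variant.nuclei.append(
                HyperfineNucleus(
                    isotope="13C",
                    spin_quantum_number=0.5,
                    a_iso=hfccs[site],
                    n_equivalent=1,
                    attached_to=0,
                    site=site,
                    natural_abundance=p,
                )
            )
            components.append(IsotopomerComponent(variant, w, site=site))
    return components


def stick_spectrum(system: SpinSystem, B0: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
    """All transition offsets (MHz, about the mean-g resonance) and weights.

    Enumerates every nuclear configuration of the system's equivalent-group
    nuclei with its statistical weight and concatenates the exact transition
    lists.
    """
    system.validate()
    if B0 is None:
        B0 = system.center_field_mT()
    g_mean = float(np.mean([e.g_iso for e in system.electrons]))
    nu0 = MHZ_PER_MT * g_mean * B0

    configs, probs = enumerate_configs(system)
    ts = batched_transitions(system, B0, configs, probs)
    return ts.frequencies - nu0, ts.intensities


def enumerate_configs(system: SpinSystem) -> tuple[list[tuple], np.ndarray]:
    """All nuclear-projection configurations with statistical weights."""
    groups = [group_projections(nuc) for nuc in system.nuclei]
    configs: list[tuple] = []
    probs: list[float] = []
    for combo in itertools.product(*[range(len(ms)) for ms, _ in groups]):
        configs.append(tuple(groups[k][0][idx] for k, idx in enumerate(combo)))
        probs.append(
            float(np.prod([groups[k][1][idx] for k, idx in enumerate(combo)]))
            if groups
            else 1.0
        )
    return configs, np.asarray(probs)


def simulate_isotropic(
    system: SpinSystem,
    axis: np.ndarray,
    lineshape: LineShape,
    derivative_order: int = 1,
    abundance: float = 0.0,
    site_carbon_counts: Optional[Mapping[str, int]] = None,
    hfcc_table: Optional[Mapping[str, float]] = None,
) -> Spectrum:
    """Simulate the isotropic first-derivative spectrum on a frequency axis.

    ``axis`` holds frequency offsets in MHz about the mean-g resonance.
    With ``abundance`` > 0 the single-13C isotopomer expansion is included,
    producing the natural-abundance satellite lines.
    """
    axis = np.asarray(axis, dtype=float)
    lineshape.validate()
    step = abs(axis[1] - axis[0])
    if step > lineshape.narrowest / 4.0:
        warnings.warn(
            f"axis step {step:.3g} MHz resolves the narrowest width "
            f"{lineshape.narrowest:.3g} MHz with fewer than 4 points",
            stacklevel=2,
        )
    if abundance > 0:
        components = isotopomer_expansion(
            system, site_carbon_counts, abundance, hfcc_table
        )
    else:
        components = [IsotopomerComponent(system, 1.0, site=None)]

    all_pos: list[np.ndarray] = []
    all_wt: list[np.ndarray] = []
    for comp in components:
        pos, wt = stick_spectrum(comp.system_variant)
        all_pos.append(pos)
        all_wt.append(wt * comp.weight)
    y = broaden(axis, np.concatenate(all_pos), np.concatenate(all_wt), lineshape, derivative_order)
    return Spectrum(
        axis=axis,
        intensity=y,
        axis_unit="MHz",
        derivative_order=derivative_order,
        mw_frequency=system.mw_frequency,
        metadata={"kind": "isotropic", "abundance": abundance},
    )


def satellite_positions(
    site: str,
    J: float,
    hfcc_table: Optional[Mapping[str, float]] = None,
    mw_frequency: float = 9.4,
) -> dict:
    """13C satellite line offsets (MHz about the centre) for one site vs J.

    Returns the exact allowed transition offsets and intensities of the
    two-electron single-13C isotopomer together with the apparent satellite
    splitting.  At J = 0 the satellites form the full doublet (split a); for
    |J| >> a the split is halved; in between four satellite lines appear.
    """
    hfccs = dict(hfcc_table or C13_HFCC)
    if site not in hfccs:
        raise ValidationError(f"unknown 13C site {site!r}; known: {sorted(hfccs)}")
    a = hfccs[site]
    from .hamiltonian import _two_spin_one_nucleus

    system = _two_spin_one_nucleus(a, J, mw_frequency)
    pos, wt = stick_spectrum(system)
    order = np.argsort(pos)
    return {
        "offsets": pos[order],
        "intensities": wt[order],
        "splitting": effective_satellite_splitting(J, a),
        "site": site,
        "a_iso": a,
        "J": J,
    }
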