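# Methods

This document records the physical model, conventions and numerical choices
implemented in `spinpair`.

## Units and conventions

- All couplings, frequencies and line widths are in **MHz**; magnetic fields
  in **mT**; distances in **nm**; temperatures in **K**.
- Field-frequency conversion uses `MHZ_PER_MT = 13.9962` (free-electron
  value g·μB/h at g = 2.0023); individual `g_iso` values scale it.
- Spectra are **first-derivative** cw EPR traces unless noted;
  `Spectrum.absorption()` integrates to absorption mode.
- Line widths are quoted as **peak-to-peak** widths of the derivative line:
  for a Gaussian, σ = ΔBpp/2; for a Lorentzian, γ = √3·ΔBpp/2.

## Spin Hamiltonian

For electrons i with resonance offsets ν_i (from g_iso and hyperfine fields)
and pair couplings (J, D):

```
H = Σ_i ν_i S_iz
  + Σ_{i<j} [ J_ij (S_iz S_jz + ½(S_i+ S_j- + S_i- S_j+))        (exchange, J S·S)
            + d_ij (S_iz S_jz − ¼(S_i+ S_j- + S_i- S_j+)) ]      (dipolar, secular + pseudo-secular)
```

with the orientation-dependent dipolar coefficient

```
d_ij(θ) = D_ij (1 − 3 cos²θ),
```

θ the angle between the inter-spin vector and the field. The high-field
approximation drops non-secular terms (valid when the Zeeman interaction
dominates all couplings, as at X band for trityls).

Nuclei are treated **classically secular**: each nuclear spin projection
m_I shifts its attached electron by `a_iso·m_I` (liquid) and configurations
are enumerated with their statistical weights. This is exact for the
transition *positions* of I = 1/2 nuclei in the high-field limit and avoids
diagonalizing the full electron-nuclear space. Equivalent nuclei are
composed by total projection with binomial/multinomial weights.

Transition frequencies and intensities come from exact diagonalization
(`numpy.linalg.eigh`, batched over nuclear configurations and orientations
as stacked matrices). Intensities are `|⟨f|Σ_i S_ix|i⟩|²` over
upper-triangle eigenstate pairs; their sum is the conserved quantity
`Tr(Sx²)/2` (= 1 for two S = 1/2 electrons), independent of J and D —
used as an invariant test. A relative intensity floor (default 1e-6)
discards forbidden transitions.

## Coupling regimes

With Δω the difference of the two electrons' resonance frequencies, the
regime ratio is `|J − D/2| / |Δω|`:

- **weak**: ratio ≤ 0.1 — first-order doublets,
- **strong**: ratio ≥ 10 — singlet/triplet limit,
- **intermediate**: in between — no closed form; only exact diagonalization
  of the full Hamiltonian describes the spectrum.

### AB quartet (liquid, one pair)

For two electrons split by Δν, each doublet of the quartet sits at

```
centre ± (C ± J/2),   C = ½ √(Δν² + J²).
```

Exact diagonalization reproduces this closed form to < 1e-9 MHz over random
(J, Δν) draws (oracle test). Outer-line intensities scale as ~(Δν/2J)² and
vanish in the strong limit.

### Satellite halving

A `13C` hyperfine coupling `a` detunes the labelled electron by ±a/2. The
apparent satellite splitting observed about the central line is

```
Δν_app(J, a) = a/2 + √(a²/4 + J²) − J,
```

which interpolates continuously from `a` (J = 0) to `a/2` (J ≫ a); the
approach to the strong limit is ~a²/8J. The same mechanism applied to small
tether protons (`a ≈ 0.3 MHz`, J ≈ 77 MHz) halves the multiplet spacing to
0.15 MHz and doubles the apparent number of coupling protons.

## Powder spectra

Frozen-solution spectra average transitions over orientations with a
Gauss-Legendre grid in cosθ (`PowderGrid(n_theta)`; an optional φ product
grid exists for completeness, the Hamiltonian here is axial). Each mixture
component is normalized to unit summed transition weight before weighting,
so a `MixtureModel` is exactly the fraction-weighted sum of its components'
spectra.

Closed-form doublet offsets (from the centre) at one orientation:

- **weak**: `|d(θ) + J| / 2` with J signed — exchange adds to or subtracts
  from the dipolar shift; at θ = π/2 this is `|D + J|/2`, at θ = 0
  `|−2D + J|/2`.
- **strong**: `|1.5 d(θ)| / 2` — the triplet manifold rescales the dipolar
  splitting by 3/2; exchange no longer shifts the allowed transitions.
- **full**: exact diagonalization with explicit Δω; converges to the weak
  form for Δω ≫ |J|, |D| and to the strong form for Δω → 0 (verified in
  tests).

The strong-coupling Pake pattern is therefore **stretched by 1.5**: its
perpendicular singularities lie 50% further out than the weak-coupling ones
at equal D (reported as `t6`; the residual ~0.3% deviation from exactly 50
in the acceptance value is finite-grid/kernel extraction bias, not physics).

Because two *identical* electrons have Δω = 0 even at J = 0, a true
weak-coupling reference pattern is realized in tests by detuning one
electron far beyond D with a spectator nucleus (a = 2000 MHz); the
undetuned electron then shows the unstretched doublet.

### Singularity extraction

`pake_singularities` integrates the derivative trace, finds the dominant
absorption maxima pair flanking the centre (ν⊥, refined by parabolic
interpolation), then locates the outer shoulders (ν∥) as the strongest
steep-descent feature beyond each maximum on a Savitzky-Golay-smoothed
slope, with a noise-adaptive threshold (median-absolute-deviation of the
wing slope) and a guard region excluding the maximum's own flank. The ν∥
edge carries only ~1% of the derivative peak-to-peak amplitude, so its
detection is reliable at SNR ≳ 50 but not at substantially higher noise.

## Distances

The point-dipole relations:

```
weak:    D = 52.01 MHz nm³ / r³
strong:  D_apparent = 1.5 · 52.01 / r³
```

The strong form is for splittings read directly off a stretched pattern.
Misreading a strong-coupling pattern with the weak formula biases distances
by `1.5^(−1/3) ≈ 87.4%` (`apparent_distance_bias`). The constant 52.01
corresponds to g = 2.00; `distance.py` also exposes the g-dependent
constant `μ0 μB² g1 g2 / (4π h) = 12.9801 · g1 g2 / 4` as an opt-in for
non-trityl g values.

## Isotopomers and satellites

Natural-abundance `13C` (1.07%) isotopomers are expanded statistically:
the all-`12C` parent plus every single-`13C` species, grouped by symmetry
site (per-trityl counts: ipso 1, ortho 3, meta 3, para 3 aromatic carbon
classes with distinct couplings). Multi-`13C` species (< 6% total weight)
are neglected. Each single-`13C` isotopomer's spectrum comes from the same
exact machinery with the labelled electron detuned, so satellite positions
automatically follow the halving law above.

## Fitting

All fit-shaped components are scikit-learn-style estimators (`fit`,
trailing-underscore attributes); thin functional wrappers are provided.

- **`SpectrumFitter`** — full-spectrum least squares against the exact
  simulation, parameters J, a_H, Gaussian/Lorentzian widths and monoradical
  signal fraction. Because the objective is rugged in J (multiplet
  registration), the fitter alternates a profiled J scan (amplitude-projected
  cost on a decimated axis, coarse 2 MHz then fine 0.25 MHz steps) with
  Levenberg-Marquardt refinement (`lmfit`), up to 3 rounds or until J moves
  by less than the fine step. Standard errors come from the LM covariance.
- **`SatelliteJEstimator`** — fits J to observed satellite offsets of
  several sites via the closed form; grid search plus bounded scalar
  refinement, curvature-based standard error. When the observation is in
  the deep strong-coupling limit (offsets at a/4), the objective has its
  optimum at the search bound with vanishing slope; the estimator flags
  this (`flat_`), warns, and reports only a lower bound on J.
- **`TemperatureTrend`** — ordinary least squares J(T) via
  `scipy.stats.linregress`; predictions outside the measured temperature
  range are flagged and warned as extrapolations (e.g. extrapolating J to
  the glass transition, estimated as Tg ≈ 2/3 of the melting point).

### Identifiability

With the model's Voigt profile, the Gaussian and Lorentzian width estimates
are strongly anti-correlated (Cramér-Rao correlation ≈ −0.96). Parameter
recovery to a few percent at SNR 50 requires the 0.15 MHz multiplet to be
resolved, i.e. component widths ≲ 0.05 MHz (typical for trityls) and an
acquisition axis dense enough to sample them (the recovery studies use
±12.5 MHz with 65536 points).

## Synthetic compounds

Built-in fixtures (monoradical `1a`; biradicals `2a`, `2b`, `4a`, `4b`;
triradical `3a`):

| | J (MHz) | D (MHz) | tether protons | monoradical fraction |
| --- | --- | --- | --- | --- |
| 2a/2b/3a | 0 | 1.2 | — | 0 |
| 4a | 77 | 7.0 | 6 × 0.3 MHz | 0.15 |
| 4b | 75 | 7.0 | 4 × 0.26 MHz | 0.05 |

Liquid-mode fixtures set D = 0 (rotational averaging); frozen mode uses
wide Gaussian/Lorentzian widths (2.36/1.00 MHz) into which the unresolved
proton structure is folded. `4a`/`4b` carry linear J(T) anchors for the
temperature-trend workflow. `generate_spectrum` adds Gaussian noise with a
standard deviation given relative to the noise-free peak-to-peak amplitude
(`noise_sd = 0.02` ≙ SNR 50), an optional polynomial baseline, and records
the exact generating truth in the spectrum metadata; generation is
deterministic per seed (`numpy.random.default_rng`).

## Numerical choices

- Batched `eigh` over stacked Hamiltonians (orientations × nuclear
  configurations) rather than Python loops.
- Broadening convolves stick spectra with unit-area Gaussian/Lorentzian
  derivative kernels on a uniform axis; a resolution warning is emitted if
  the axis step exceeds a quarter of the narrowest width. Lorentzian wings
  truncated at the window edge cost ~0.4% area over a ±20 MHz window —
  physical, not a normalization error.
- Degenerate transitions are merged by frequency tolerance before
  broadening.

## Limitations

- High-field, isotropic-g model: no g anisotropy, no non-secular dipolar
  terms, no zero-field regime.
- Nuclei are classically secular: nuclear flip-flop (forbidden) transitions
  and second-order nuclear shifts are absent.
- Multi-`13C` isotopomers are neglected (< 6% of the ensemble).
- The intermediate-regime closed forms do not exist by construction; the
  package deliberately raises and directs to full diagonalization.
- The triradical is treated as three pairwise-coupled electrons; no
  three-spin correlated relaxation effects.
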