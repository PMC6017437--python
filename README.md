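# spinpair

Exact simulation and analysis of continuous-wave EPR spectra of exchange- and
dipolar-coupled trityl radical pairs and triads.

Tethered trityl bi- and triradicals show cw EPR spectra governed by the
interplay of the isotropic exchange coupling `J`, the dipolar coupling `D`,
and the small hyperfine couplings of the tether and aromatic nuclei.
`spinpair` builds the high-field spin Hamiltonian of such systems,
diagonalizes it exactly, and provides the closed-form limits, lineshape
machinery, distance conversions and least-squares fitting needed to analyze
both room-temperature (liquid) and frozen-solution (powder) spectra:

- **Liquid spectra** — isotropic multiplets, statistical `13C` isotopomer
  expansion at natural abundance, and the continuous `J`-dependent migration
  of satellite lines between the weak (`a`) and strong (`a/2`) coupling
  limits.
- **Powder spectra** — orientation-averaged Pake patterns from exact
  diagonalization at every orientation, including the factor-1.5 stretch of
  the strong-coupling pattern, with singularity extraction
  (`nu_perp`, `nu_par`) from noisy first-derivative data.
- **Distances** — `D = 52.01 MHz nm^3 / r^3` in the weak regime,
  `D = 1.5 * 52.01 / r^3` for apparent splittings read off strong-coupling
  patterns, and the 87% distance bias incurred by misreading a stretched
  pattern with the weak formula.
- **Fitting** — scikit-learn-style estimators for spectrum fitting,
  satellite-based `J` determination, and the linear temperature dependence
  of `J` with flagged extrapolation (e.g. to the glass transition).
- **Synthetic data** — deterministic, seedable spectrum generation for a
  set of built-in model compounds with recorded ground truth.

## Worked example: recover parameters from a noisy liquid spectrum

```python
import numpy as np
from spinpair.synthetic import make_fixture, generate_spectrum
from spinpair.fitting import SpectrumFitter

fx = make_fixture("4a")                       # biradical, J = 77 MHz
axis = np.linspace(-12.5, 12.5, 65536)        # MHz around the centre
spec = generate_spectrum(fx, mode="liquid", noise_sd=0.02, seed=1, axis=axis)

fitter = SpectrumFitter(compound=fx, mode="liquid").fit(spec)
print("converged:", fitter.converged_)
for name, (val, err) in fitter.params_.items():
    print(f"{name:22s} {val:8.4f} +/- {err:.4f}")
```

Output:

```
converged: True
J                       75.6839 +/- 0.8735
a_H                      0.3001 +/- 0.0001
gaussian_width           0.0496 +/- 0.0007
lorentzian_width         0.0501 +/- 0.0006
monoradical_fraction     0.1503 +/- 0.0015
```

The generating truth is `J = 77`, `a_H = 0.3`, widths `0.05/0.05` and a 15%
monoradical contamination; every parameter is recovered within a few percent
at a noise level of 2% of the peak-to-peak amplitude.

Other common operations:

```python
from spinpair.hamiltonian import classify_regime, effective_satellite_splitting
from spinpair.distance import distance_from_D

classify_regime(J=77.0, D=7.0, delta_omega=4.2)
# |J - D/2|/|delta_omega| = 17.5 -> strong coupling

effective_satellite_splitting(77.0, 0.3)
# 0.1501...  (strong coupling halves the 0.3 MHz proton splitting)

distance_from_D(7.0, "strong")
# r = 2.234 nm; misreading with the weak formula would give 1.951 nm (87.4%)
```

## Command line

The `spinpair` entry point wraps the main operations:

```
$ spinpair distance --d 1.2 --regime weak
D = 1.2 MHz (weak): r = 3.513 nm [D = 52.01/r^3]

$ spinpair regime --j 77 --d 7 --delta-omega 4.2
|J - D/2|/|delta_omega| = 17.5 (delta_omega = 4.2 MHz) -> strong coupling

$ spinpair fitj --offsets 8.5972,6.754 --sites ipso,ortho
J = 77.00 +/- 0.00 MHz (objective 5.05e-10)
```

`spinpair simulate`, `spinpair powder`, `spinpair fixture`, `spinpair
fitspec` and `spinpair jtemp` cover spectrum simulation, fixture
materialization, file-based fitting and the `J(T)` trend; see `--help` on
each subcommand.

## Module map

| Module | Contents |
| --- | --- |
| `spinpair.systems` | `SpinSystem`, `ElectronSpin`, `HyperfineNucleus`, `PairCoupling`, YAML I/O |
| `spinpair.hamiltonian` | Hamiltonian construction, exact/batched diagonalization, regime classification, satellite closed form |
| `spinpair.liquid` | Isotropic multiplets, isotopomer expansion, satellite positions |
| `spinpair.powder` | Orientation grids, powder averaging, Pake closed forms, singularity extraction, mixtures |
| `spinpair.spectrum` | Lineshapes, derivative broadening, `Spectrum` container, file I/O |
| `spinpair.distance` | Distance/coupling conversions and the apparent-distance bias |
| `spinpair.fitting` | `SpectrumFitter`, `SatelliteJEstimator`, `TemperatureTrend` |
| `spinpair.synthetic` | Built-in compound fixtures and the noisy-spectrum generator |

The physics, conventions and numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Reproducing results

Run the full test suite (includes the acceptance tests, about two minutes of
which is a 10-seed parameter-recovery study):

```
python -m pytest tests/
```

Recompute the headline numbers and write them to JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which produces

```json
{"t1": 3.51, "t2": 2.23, "t4": 0.15, "t6": 50.3}
```

- `t1` — distance (nm) from `D = 1.2 MHz`, weak-coupling relation,
- `t2` — distance (nm) from an apparent `D = 7.0 MHz`, strong-coupling relation,
- `t4` — apparent proton splitting (MHz) at `J = 77 MHz`, `a = 0.3 MHz`,
- `t6` — percentage by which strong-coupling Pake singularities exceed the
  weak-coupling ones at equal `D`.

All targets are deterministic (closed forms or noise-free simulations); the
`--seed` flag only labels the run.
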