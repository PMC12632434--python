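# mesohydra

Analysis tools for the structure and water dynamics of **inverse
bicontinuous cubic lipid mesophases** (IBCPs) — the gyroid (Ia3̄d),
diamond (Pn3̄m) and primitive (Im3̄m) phases whose lipid bilayer drapes a
triply periodic minimal surface and confines water in two
interpenetrating channel networks.

The package is aimed at experimentalists and simulators who combine
small-angle X-ray scattering (SAXS), far-infrared/THz absorption
spectroscopy, and atomistic coordinate frames to ask how soft
nanoconfinement reshapes the hydrogen-bond (HB) network of water.

## What it computes

**SAXS indexing and mesophase geometry** (`mesohydra.saxs`).
Bragg peaks follow d<sub>hkl</sub> = a/√N with N = h²+k²+l² restricted by
the space group ({6,8,14,16,…} for Ia3̄d, {2,3,4,6,…} for Pn3̄m,
{2,4,6,8,…} for Im3̄m). Peaks are detected, assigned, and the lattice
parameter *a* fit by a through-origin regression of q on 2π√N.
Minimal-surface algebra then gives the water-channel radius
r = √(A₀/(−2πχ))·a − l, the lipid length l from
φ_L = 2A₀(l/a) + (4πχ/3)(l/a)³, and the interfacial water fraction
f<sub>w,int</sub> = (−0.543·K₀ − 2.092)/Γ with Γ = f_w·a³/(4π|χ|),
where A₀ is the dimensionless minimal-surface area per unit cell and χ
its Euler–Poincaré characteristic (3.091/−8, 1.919/−2, 2.345/−4).

**THz spectral decomposition** (`mesohydra.thz`).
Raw ATR intensities become absorption coefficients via the Beer–Lambert
law with the evanescent effective thickness
d_s = λ/(2π√(n_C²sin²θ − n_s²)); the lipid-mixture spectrum is
subtracted by volume fraction; and Δα(ν) is decomposed into a
Debye-type low-frequency line, two fixed high-frequency oscillators and
two modified damped-harmonic-oscillator (DHO) modes — the
intermolecular HB **stretching** (~150 cm⁻¹) and **libration**
(~410 cm⁻¹) modes of water. Mode widths map to lifetimes via
τ = 1/(ω₀c), and ln τ vs 1/T yields Arrhenius activation energies
E_a = slope·R.

**Hydrogen-bond profiling** (`mesohydra.hbond`).
The canonical geometric criterion (donor–acceptor distance ≤ 0.35 nm
and H–donor–acceptor angle ≤ 30°, both configurable) is evaluated with
a periodic neighbour list that reproduces the all-pairs result exactly.
Per-water bond counts are binned by distance from the membrane midplane
to give n_HB(z), the bulk-recovery distance x_c, and the Arrhenius
temperature dependence of the mean bond count.

**Synthetic data** (`mesohydra.synthetic`) generates SAXS profiles, THz
temperature series and slab coordinate frames with recorded ground
truth, so the whole pipeline is testable without measured data.

## Worked example

```python
import numpy as np
from mesohydra import saxs, thz
from mesohydra.synthetic import gen_saxs, gen_thz_series

# --- SAXS: index a synthetic diamond-phase profile and derive geometry
profile, truth = gen_saxs(group="Pn3m", a=12.0, n_peaks=4, noise_sd=0.01, seed=7)
peaks = saxs.detect_peaks(profile)
assignment, table = saxs.index_phase(peaks, temperature=298.0)
l = saxs.lipid_length(0.5, assignment.lattice_parameter_nm, assignment.space_group)
r, d = saxs.channel_diameter(assignment.lattice_parameter_nm, l, assignment.space_group)

# --- THz: fit a 15-temperature series and extract activation energies
spectra, _ = gen_thz_series(seed=1)
init = thz.SpectralModel(
    a_LF=165.0, a_HF=6600.0,
    stretching=thz.DHOMode(1980.0, 161.7, 209.0),
    libration=thz.DHOMode(4180.0, 453.2, 308.0))
series = thz.analyze_series(spectra, init)
```

This prints (via the obvious `print` statements):

```
peaks (1/A): [0.074  0.0907 0.1046 0.1282]
phase: Pn3m  a = 12.005 nm  residual = 6.39e-04
lipid length l = 1.629 nm, channel diameter d = 6.124 nm
Gamma = 34.42, interfacial water fraction f_w,int = 0.0425
stretching: E_a = 3.63 kJ/mol (r^2 = 0.972)
libration: E_a = 7.43 kJ/mol (r^2 = 0.999)
tau_stretching(298 K) = 176.8 fs
tau_libration(298 K) = 119.4 fs
```

Reading: the four peak positions sit in √2:√3:√4:√6 ratio, so the
profile indexes as Pn3̄m with a 12.0 nm cell; at 50% lipid the water
channels are ~6.1 nm wide and ~4% of the water is interfacial. The THz
series (generated with E_a = 3.5 and 7.4 kJ/mol) returns both
activation energies within the fit uncertainty, with the stretching
mode slower (longer τ) but roughly two-fold less temperature-sensitive
than libration — the signature the decomposition is designed to
resolve.

A command-line surface wraps the same functions:

```bash
mesohydra simulate thz --seed 1 --out sim/
mesohydra thz-fit sim/spectrum_*.csv --out fit.json
mesohydra run --config config.yaml     # chained simulate -> index -> fit -> correlate
```

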