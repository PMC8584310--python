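# nanorelease

Analysis toolkit for drug release from carbon-nanotube carriers. It
serves two audiences: experimentalists who measure cumulative release
of a drug (e.g. doxorubicin) from a nanotube carrier by UV-Vis
spectrophotometry and want to identify the release kinetics and
transport mechanism, and simulators who have boxed particle
configurations of a nanotube plus ligand molecules and want the
adsorption and aggregation statistics that describe carrier loading.

## What it computes

**Release kinetics.** Seven classical dissolution models are fitted to
a cumulative release curve C(t):

| model          | C(t)                              |
|----------------|-----------------------------------|
| zero order     | C₀ + K₀·t                         |
| first order    | C_d·(1 − e^(−K₁t))                |
| second order   | C_d − 1/(1/C_d + K₂t)             |
| Higuchi        | K_H·√t                            |
| Hixson–Crowell | C_d − (C_d^⅓ − K_HC·t)³           |
| Weibull        | C_s·(1 − e^(−(t−T)^b / a))        |
| power law      | K·tⁿ (Korsmeyer–Peppas)           |

Fits are nonlinear least squares on the natural scale (classical
linearized regressions are available), each reporting R², adjusted R²
and AICc; `fit_all` ranks the models (AICc by default, plain R² on
request). The transport mechanism is called from the power-law
exponent *n* (n < 0.5 Fickian diffusion, 0.5 ≤ n < 1 anomalous, n = 1
Case II, n > 1 Super Case II) or from the Weibull shape factor *b*
(b ≤ 0.75 Fickian, 0.75 < b ≤ 1 combined, b > 1 complex). A small
companion module converts absorbances to concentrations through a
linear standard curve and does the percent-adsorbed / percent-released
bookkeeping with explicit units.

**Configuration statistics.** On an orthorhombic (optionally periodic)
box holding nanotube atoms and ligand molecules the package computes
single-linkage contact aggregates (any inter-atomic distance below a
cutoff, 0.35 nm by default, minimum-image convention), the aggregate
count and mean size, the percentage of molecules adsorbed by the
nanotube (membership of the nanotube-containing cluster), and the
percentage adsorbed *inside* the tube by the ring/virtual-sphere
method: the tube is split into axial carbon rings, a sphere is centred
on each ring's centre of mass, molecules whose centre of mass falls in
any sphere are collected and deduplicated. XYZ (with a JSON molecule
map) and GRO files are supported.

**Synthetic ground truth.** A generator produces noisy release curves
from any of the models at the standard 1/3/5/10/20/30-min grid, and
boxed configurations — zigzag-lattice nanotubes (three concentric
walls near 6.42/7.12/7.83 nm by default, 20 nm long, in a
20 × 80 × 20 nm box) with controlled populations of free, aggregated,
surface-adsorbed and inside-adsorbed bead-chain molecules — whose
intended statistics are exact by construction, so every analysis
routine can be validated against known truth.

## Worked example

```sh
nanorelease simulate-release --noise-sd 0.01 --seed 3 --out curve.csv
nanorelease fit-kinetics curve.csv
```

generates a noisy six-point release curve from the reference power-law
parameters (K = 0.7379, n = 0.088) and fits all seven models. The
report ranks `power_law` first with K̂ = 0.7413, n̂ = 0.0845 and
R² = 0.976, and calls the mechanism `fickian` from n̂ < 0.5 — the
fitted exponent recovers the generating one to within the noise, and
the call matches what such a flat, diffusion-limited release profile
should produce.

```sh
nanorelease simulate-config --n-free 6 --n-surface 3 --n-inside 1 \
    --aggregate-size 2 --walls 3 --seed 5 --out cfg.gro
nanorelease analyze-config cfg.gro
```

writes a three-wall-nanotube configuration with 12 molecules and
reports, per frame:

```
frame,n_aggregates,mean_size,pct_adsorbed,pct_inside
0,8,1.5,33.333333333333336,8.333333333333334
```

8 aggregates (the nanotube cluster with its 4 adsorbed molecules, one
2-molecule aggregate, six free monomers), 4/12 = 33.3% adsorbed and
1/12 = 8.3% inside — exactly the generator's intended labels.

The same functionality is available as a library
(`nanorelease.fit_all`, `nanorelease.summarize`, ...); see the module
docstrings and `docs/methods.md`.

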