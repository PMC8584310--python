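# Methods

## Release kinetics

### Model forms and conventions

All seven models are implemented on the natural (untransformed) scale
with time in minutes and cumulative release either as an amount (any
concentration-like unit) or as a fraction of the equilibrium amount
C∞. Two printed-form ambiguities are resolved explicitly:

* **Second order.** The textbook rate law d(C_d − C)/dt = −K₂(C_d − C)²
  integrates to 1/(C_d − C_t) = 1/C_d + K₂t, which increases with time
  as release proceeds. A variant with the opposite sign on K₂t (which
  makes release *decrease* with time and can cross a pole at
  t = 1/(K₂C_d)) circulates in the literature; it is available via
  `predict(..., printed_sign=True)` but is not the default.
* **Weibull exponent grouping.** The scale parameter divides the
  power, exp(−(t − T)^b / a), which is the classical dissolution
  Weibull where *a* sets the timescale and *b* the curve shape
  (exponential at b = 1, sigmoid above, parabolic below). The
  alternative grouping exp(−((t − T)/a)^b) is available via
  `scale_inside=True`.

Other conventions: zero-order C₀ is a free parameter (physically it is
usually 0; fix it by bounding if needed); the Hixson–Crowell cube-root
form is clipped at C_d once the root reaches zero (release complete);
the Weibull lag time T is bounded by the first observation; the
power-law and Weibull models operate on the fraction scale, so amount
curves must carry C∞.

### Fitting

Nonlinear least squares (trust-region reflective, bounded, tolerances
1e-15) from deterministic data-driven starts: log–log regression for
the power law and Higuchi, anchored linearized regressions for the
first/second-order and cube-root models, and (C_s = max value, T = 0,
a = median t, b = 1) for the Weibull, with two additional shape starts
b ∈ {0.5, 2} because the four-parameter surface is the only one with
meaningful local minima on six-point curves. The classical linearized
regressions are also exposed (`scale="linearized"`); R² is always
reported on the scale that was fitted, because an R² computed on a
log-transformed response is not comparable to one on the natural
response. The anchored linearizations need the total releasable
amount; fractions anchor at 1, amounts at C∞ when given, otherwise at
5% above the largest observation (an approximation — on noiseless data
only the true total makes the transformed response exactly linear).

Degenerate curves (all values equal) leave R² undefined (NaN sentinel,
flagged); non-convergence is reported, never dropped, and ranked last.

### Model ranking

`fit_all` ranks by **AICc**, the small-sample-corrected Akaike
criterion, with ties broken by fewer parameters and then model name.
The choice matters: on six-point curves the four-parameter Weibull can
absorb measurement noise and beat the true two-parameter generating
model on raw R² in roughly half of noisy draws, and even adjusted R²
(denominator n − p − 1 = 1) does not reliably protect against this.
AICc is the standard selection statistic when n/p is this small and
restores the property that the best-supported model is the
data-generating one; the correction effectively disqualifies
parameter counts within one of the sample size, which is the desired
behaviour at n = 6. Plain R² and adjusted R² are reported for every
fit, and `rank_by="r_squared"` gives the classical correlation-only
ranking.

### Mechanism thresholds

For cylindrical release geometry, the power-law exponent *n* calls the
transport mechanism: Fickian diffusion below 0.5, anomalous
(diffusion + matrix swelling) from 0.5 up to 1, Case II
relaxation-controlled transport at exactly 1 (matched within 1e-9),
Super Case II above 1. The boundary n = 0.5 belongs to the anomalous
class because Fickian is defined as *below* 0.5. The Weibull shape
factor *b* calls Fickian at or below 0.75, combined mechanisms up to
1, and a complex mechanism above 1.

## Spectrophotometric accounting

Concentrations come from a linear standard curve
(absorbance = slope·conc + intercept, 484 nm by default) fitted by
ordinary least squares; absorbances below the blank are clipped to
zero concentration with a warning. Concentrations carry explicit unit
tags (mg/mL vs µg/mL) because loading protocols routinely mix the two
scales across a 1000-fold gap. For the reference loading protocol
(100 mg carrier, 10 mL at 40 mg/mL initial, 22.5 µg/mL after
filtration) the adsorbed percentage computes to
100·(1 − 0.0225/40) = 99.94375%; note that some sources quote 99.97%
for these same numbers — the package returns the arithmetic value.
Released-mass accounting (conc × volume / loaded mass) ignores
sampling-volume depletion, as no withdrawal-replacement protocol is
modelled; a released mass exceeding the loaded mass by more than 5% is
rejected as a calibration inconsistency.

## Configuration statistics

### Aggregates and adsorption

Aggregates are single-linkage components: two molecules (or a molecule
and the nanotube) are linked iff any inter-atomic distance is strictly
below the cutoff (0.35 nm default — the usual heavy-atom contact
criterion), with minimum-image distances on the orthorhombic box. The
cutoff must not exceed half the smallest box edge (checked).
Single linkage is the natural reading of aggregation by contact:
molecules bound to the nanotube through other molecules count as
adsorbed, which matches treating the nanotube + ligand complex as one
aggregate. The nanotube-containing cluster is included in the
aggregate count and mean size by default (`count_cnt_cluster=False`
excludes it); cluster sizes count ligand molecules only. Labels are
deterministic (ordered by lowest member index), so permuting input
molecules permutes nothing observable.

Centres of mass are mass-weighted and computed after unwrapping each
molecule relative to its first atom, so configurations wrapped across
the periodic boundary give identical statistics to unwrapped ones.

### Inside-tube counting

The ring/virtual-sphere method bins tube atoms into axial carbon rings
(0.213 nm bins — 3/2 of the 0.142 nm C–C bond, the zigzag ring
repeat), takes each ring's centre of mass, and counts a molecule as
inside when its centre of mass lies within the sphere radius of any
ring centre (duplicates collapse). For a straight tube with ring
spacing at most the sphere radius this is exactly membership of a
finite cylinder with spherical end caps; for a flexing tube the ring
centres leave the nominal axis and the two counts disagree — the
method's known counting artifact, reproduced here by generating tubes
with sinusoidal transverse bending.

The sphere radius defaults to **half** the (innermost-wall) tube
diameter, i.e. the tube's own radius: 3.21 nm for a 6.42 nm tube. A
convention in which the sphere radius equals the full diameter also
circulates; it would count molecules up to one radius *outside* the
wall as inside, which is geometrically inconsistent with "inside the
nanotube", so it is supported (`sphere_radius_mode="printed"` in the
CLI, or pass the diameter explicitly) but not default. In composite
summaries, "inside" is additionally intersected with "adsorbed"
(nanotube-cluster membership), so pct_inside ≤ pct_adsorbed always
holds and free molecules drifting through the bore are not counted.

## Synthetic generators

The release-curve generator evaluates any registered model on the
standard 1/3/5/10/20/30-min sampling grid and adds seeded
homoscedastic Gaussian noise (heteroscedastic — sd proportional to the
value — on request), clipped at zero. Fraction-kind curves whose
noiseless values exceed the tolerated ceiling of 1.05 (possible for
steep parameter draws at late times) are emitted as amounts with
C∞ = 1: numerically the identical scale, so fits are unaffected while
the fraction-range invariant stays meaningful for measured data.

The nanotube generator builds zigzag (m, 0) walls: the requested
diameter is rounded to the nearest realizable d = 0.246·m/π (at most
~0.04 nm off), every atom sits exactly on its wall radius, and rings
repeat every 0.213 nm. Three-wall tubes default to walls near
6.42/7.12/7.83 nm. The configuration generator places, in order:
surface molecules anchored 0.9 × cutoff outside a random outer-wall
atom (guaranteed contact), inside molecules anchored 0.9 × cutoff
inward of a random innermost-wall atom with the bead chain along the
axis (guaranteed contact *and* inside the bore), isolated aggregates
as straight chains of molecules with inter-molecule bead gaps of
0.85 × cutoff, and free molecules — the latter two kept more than
2 × cutoff away from everything and outside the bore region. The
2 × cutoff margins make the intended partition the unique
single-linkage solution, so the generator's truth record (labels,
partition, aggregate count/mean size, pct adsorbed/inside) is exact
rather than statistical; placement that cannot satisfy the margins
after 500 attempts raises a packing error.

Ligand molecules are rigid 3-bead chains (0.2 nm spacing, unit
masses). This is deliberate: every statistic here is a function of
coordinates and molecule grouping only, so an all-atom drug model
would change nothing but the constants. What the synthetic
configurations do **not** emulate is the physics that produces real
adsorbed states — no energetics, no dynamics, no realistic aggregate
geometry or density, no water. Passing the closure tests therefore
shows that the *analysis* is exact on configurations with known
labels; it says nothing about whether a particular force field would
produce such configurations.

Default geometry (20 × 80 × 20 nm periodic box, tube length 20 nm,
axis along y, three walls near 6.42/7.12/7.83 nm) mirrors the
simulated carrier-loading setup this package is meant to analyse; the
drug-to-carrier mass ratio of such setups (4:1 for the reference
loading protocol) is computed from the loading protocol, and molecule
counts are taken directly rather than derived from masses, since bead
molecules have no meaningful molar mass.

## Problem sizes and numerical choices

Validation workloads are sized for a desk machine: 200 curves for
parameter recovery, 100 for model selection, 100 random periodic
configurations (20–500 molecules) against the O(N²) clustering oracle,
20 straight-tube and 10 bent-tube configurations against the analytic
capsule oracle, and 50 generator-closure draws; the whole suite runs
in about a minute. Contact search uses a k-d tree with periodic boxsize
and re-filters candidate pairs to the strict `< cutoff` criterion
(tree queries are inclusive). Components come from a sparse
connected-components pass over the molecule graph. Exact-agreement
checks between the implementation and its oracles use set/label
equality, not tolerances; the generators' separation margins keep all
decisions away from floating-point boundaries.

## Known limitations

* The kinetics fits report no confidence intervals; identifiability of
  the four-parameter Weibull on six points is marginal, which is
  exactly why ranking needs a parsimony-corrected statistic.
* The anchored linearized fits depend on the assumed total; they are
  provided for comparability with classical practice, not as the
  recommended estimator.
* Multi-frame trajectory support is limited to one configuration per
  file (several files form a time series); there is no reader for
  binary trajectory formats.
* The aggregate criterion is purely geometric; no energetic or
  residence-time definition of adsorption is attempted.
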