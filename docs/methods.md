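# Methods

This note documents the models, numerical choices and limitations behind
`smds`. Everything quantitative stated here is computed by the test suite or
the acceptance script; nothing is asserted from memory of external data.

## Transport model and basis simulation

The observation channel is a rectangular duct (height H = 25 µm, width
W = 225 µm by default) carrying fully developed pressure-driven flow. The
sample stream enters flow-focused between buffer streams at a volume ratio
of ~1:8, i.e. an inlet top-hat occupying `sample_flow_fraction = 1/9` of
the width (fractional cell filling at the edges). Steady-state transport of
a species with diffusion coefficient D obeys

    u(y, z) ∂c/∂x = D (∂²c/∂y² + ∂²c/∂z²),

with zero flux through the walls; axial diffusion is negligible at the
operating Péclet numbers. Substituting the mean residence time t = x / v̄
turns this into a pseudo-time diffusion problem with spatially varying
mobility D·v̄/u(y, z).

Numerics:

* **Velocity field** — rectangular-duct Poiseuille series, 11 odd harmonics
  (overflow-safe cosh ratios), rescaled so the discrete flux matches the
  configured flow rate. A depth-averaged mode (plug flow, 1-D in y) is
  available and flagged in the metadata.
* **Grid** — cell-centered (no node on a wall, where u = 0), default
  151 × 31 cells (width × depth); the inlet stream (25 µm) spans ~17
  transverse cells at default resolution.
* **Marching** — Crank–Nicolson steps in residence time, with the first two
  steps implicit Euler (Rannacher start-up) to damp the discontinuous
  inlet profile. Steps per inter-crossing segment are chosen so the
  diffusion length added per step stays below two transverse cells, clamped
  to [12, 200]. The conservative five-point Laplacian makes the u-weighted
  mass flux exactly conserved; the drift is tracked in metadata and is at
  machine precision (tested ≤ 1e-6, observed ~1e-13).
* **Readout** — mid-height slice of the cross-section, convolved with a
  lateral Gaussian (default waist 0.3 µm) for the confocal spot, normalized
  to unit area per crossing. Stored profiles are therefore *shapes*;
  absolute amplitudes are fit parameters downstream.
* **Crossing positions** — the four scanned crossings are parameterized by
  their residence times, default {0, 10, 26, 55} s at the configured flow.
  Absolute downstream distances depend on how the channel is folded and are
  deliberately left as user configuration; `residence_time` converts
  distance to time when distances are known. Accuracy of the solver is
  established against the closed-form Fourier-series solution for 1-D
  diffusion of a slab in the depth-averaged limit (agreement < 2% in
  relative L2 per crossing, < 1% deviation from uniformity in the
  long-time limit).
* **Radius grid** — default 60 log-spaced nodes over 0.3–300 nm; the tests
  and recovery studies use 45 nodes over 0.5–300 nm with a 101 × 9 grid,
  which keeps a full basis simulation near one second at percent-level
  interpolation accuracy (verified against fresh simulations at off-grid
  radii, relative L2 < 2%).

One physical caveat found while validating: mid-height profiles are
narrower than depth-averaged ones only while the stream is still developing
(spread below ~half the uniform-limit variance W²/12). Once mass reaches
the low-velocity side-wall regions, their long local residence inflates
mid-height spreading and the ordering crosses over toward equality. The
Taylor-dispersion direction check in the tests is scoped accordingly.

## Burst search

Single-molecule transits are extracted from photon timestamp traces
(16-ps integer ticks) by the combined criterion: a burst is a maximal run
of at least `n_min` photons whose consecutive inter-photon times (IPTs),
after Lee filtering of the IPT sequence, all stay at or below `ipt_max`.
Defaults are the midpoints of the established working ranges: `ipt_max` =
0.01 ms, `n_min` = 10 photons, Lee window 3 samples; all three are exposed
as CLI flags. The Lee filter uses truncated windows at the edges and a
global noise scale σ₀ equal to the median windowed standard deviation of
the full IPT series; both choices are recorded in the burst metadata.
Whether the filter is applied to the IPT sequence or to a binned intensity
trace is not uniquely determined by practice; this implementation filters
the IPT sequence, and the choice is visible in the metadata.

Properties to be aware of:

* Burst counts are monotone nonincreasing in `n_min` unconditionally.
  Monotonicity in `ipt_max` holds in the operating regime where thresholds
  sit well above the intra-burst IPT; a threshold within a few multiples of
  the intra-burst IPT can split one transit into several qualifying runs.
* Zero-duration (single-tick) runs are rejected.
* On pure background with mean IPT ten times `ipt_max`, false positives are
  below one burst per 10 s at default settings (verified by seeded
  simulation).

## Profile fitting

Measured profiles (all crossings jointly) are fitted as
`value ≈ a·P_r(y) + b` with a global amplitude a ≥ 0 and baseline b,
where P_r is the basis shape at candidate radius r. The radius is scanned
over the basis grid (ties broken toward the smaller radius,
deterministically) and refined by parabolic interpolation of the SSE over
the three best nodes in log r.

Weighting: digital step profiles are Poisson counts, but weighting by the
observed counts (1/max(v, 1)) correlates weights with noise and biases the
radius upward by ~15–25% at the ~5,000-count scale. The fit therefore runs
uniform-weight first, then one Pearson iteration with weights
1/max(fitted expectation, 1). Residual bias in recovery studies is within
±3–4% across 1–100 nm. Continuous intensity profiles use uniform weights.

Uncertainty: a curvature (Taylor) estimate,
`var(r) = 2 σ̂² / (∂²SSE/∂r²)` with σ̂² = SSE/(n−3) from the weighted
residuals at the minimum, reported as a symmetric ± range. Coverage of this
range is ~68% in simulation (asserted between 45% and 90% over 60
replicates), and it scales as 1/√counts (asserted ×2 when counts
quadruple). Per-crossing local radius errors refit each crossing alone and
report the deviation from the global radius; a crossing whose SSE is flat
across the whole radius grid — notably the inlet crossing at zero residence
time — carries no size information and is reported as undefined rather
than zero. A per-crossing transverse registration offset (±5 µm) is
available as an opt-in nuisance parameter and recorded when used; it is off
by default.

## Oligomer brightness deconvolution

With the degree of labeling at or below one dye per monomer, burst
normalized intensity scales with the number of monomer units. The burst
intensity distribution is modeled as a skew-normal monomer (the right skew
reflects undersampling of short transits) plus Gaussians for the n-mers
whose centers are exactly n × the monomer *mean* and whose widths equal the
monomer standard deviation — only three shape parameters and the mixture
weights are free. Fitting is by maximum likelihood on unbinned intensities
(histograms are display-only); optimization alternates EM weight updates
with L-BFGS refinement of the shape using an analytic gradient, from two
starts differing in initial skewness (a wide-monomer local optimum that
swallows the dimer shoulder exists; the best likelihood wins). Species
counts are compared by BIC on the same likelihood (one weight parameter per
added species); the criterion is pluggable and reported in full.

Abundance confidence intervals are percentile bootstrap over burst
resampling (default n_boot = 1000, seeded). Each resample is *fully*
refitted — weight-EM, then two warm-started coordinate cycles over the
shape — because holding the shape at the full-sample fit measurably narrows
the intervals and drops their coverage. Interval endpoints use
non-interpolating order statistics, so a finite bootstrap sample cannot
narrow the extreme tails. In simulation at the four-species study
conditions (abundances 0.679/0.207/0.072/0.042, 10⁴ bursts), abundances are
recovered within ±0.03 and 99% intervals cover the truth in ≥95 of 100
replicates (computed with n_boot = 150 per replicate; the coverage
simulation's own scale, not the operational default).

Species gates are ±1 monomer σ around each center; the capture fraction of
a pure Gaussian component under this gate is erf(1/√2) ≈ 68.3%, which the
tests assert against the closed-form integral. The N_min threshold sweep
runs the burst search once at the smallest threshold and filters bursts per
threshold value, marking undersampled entries (< 50 bursts by default)
instead of fitting them.

## Mixtures and nanoscale clusters

Fibril/bulk splitting applies a Savitzky–Golay filter (window 11 bins,
order 3 at 1-ms binning — defaults recorded in the output) and attributes
maximal runs above a count-rate threshold (e.g. 250 kHz), padded by one
window on each side, to large assemblies; the remainder is bulk. Spike
counts per position feed a digital step profile, bulk means a continuous
profile, and each is sized independently.

Nanocluster events are maximal runs of 1-ms bins above mean + k·σ (default
k = 5) of the bulk, with the mean and σ estimated robustly (median and
1.4826 × MAD) so the rare events cannot inflate their own threshold.
Per-crossing event histograms are fitted with independent Gaussians; the
*diffusion distance* at each crossing is half the fitted FWHM, the t = 0
width is removed in quadrature, and the net distances are least-squares
fitted with x = √(2 D t) (closed-form slope: √(2D) = Σ x√t / Σ t), after
which Stokes–Einstein gives R_H. Note the convention: half-FWHM equals
1.1774 × the Gaussian σ, so this distance definition absorbs a factor
2·ln 2 relative to the standard-deviation convention; the synthetic cluster
generator spreads its event clouds consistently with the same definition
(σ² grows by 2Dt/(2 ln 2)), and an absolute calibration of the distance
convention against an instrument response is outside the generator's scope.
The per-seed scatter of the recovered radius is dominated by the quadrature
normalization at the early crossings (where broadening is comparable to the
t = 0 width); the 20-seed mean at 500 events/crossing recovers a 120-nm
truth within 15%.

Event counts convert to flux as F = (N / T_obs) / detection_efficiency; the
geometric detection efficiency is instrument calibration and must be
supplied explicitly — there is deliberately no default. Flux converts to
particle concentration as c = F/(Q·N_A) and to volume fraction as
φ = c·N_A·(4/3)πr³; monomers-per-cluster bounds are packing × (r_c/r_m)³
with the pure-protein ceiling reported alongside.

## Binding isotherm

A labeled antigen at fixed total concentration titrated with an unlabeled
bivalent antibody is modeled with two independent, identical sites of site
dissociation constant K_d. The exact conservation system is solved for the
free-site concentration by bracketed root finding (relative tolerance
1e-14); no excess-titrant approximation is made, because at picomolar
antigen (comparable to K_d) depletion shifts the apparent midpoint — a
hyperbolic (Langmuir) fit to the same synthetic data misestimates K_d by
>10% while the exact fit recovers it to <1% (regression-guarded). The
measured effective radius is the mole-fraction-weighted mean of the free
and bound antigen radii; antigen on a singly-occupied antibody is assigned
the bound radius (the 150-kDa antibody dominates the complex's
hydrodynamics either way). The weighting is isolated in one function so a
diffusion-weighted alternative can be swapped in. K_d, r_free and r_bound
are fitted by weighted least squares with the K_d uncertainty from the
Jacobian covariance (delta method on log K_d).

## Synthetic-data generator

The generator shares the basis solver's concentration fields with the
fitter but produces noise, detection and burst structure independently:

* transits per position are Poisson with rate = local number density ×
  mean velocity × effective detection area (default 0.3 µm²); the local
  density distributes the conserved inlet line density (c·N_A·f·W) along
  the basis shape;
* each transit lasts detection_length / v̄ (default 1 µm → ~0.2 ms at
  100 µL/h) and emits Poisson photons at brightness × labeled units;
  background photons are Poisson at the configured rate; all timestamps are
  quantized to 16-ps ticks;
* default per-unit brightness is 1000 photons/ms during a transit (~1 MHz
  peak count rate, appropriate for bright single fluorophores at the
  operating excitation power). This keeps the intra-burst IPT an order of
  magnitude below the default `ipt_max`, the regime in which one transit
  maps to one cohesive burst; at a few hundred photons/ms the burst search
  begins to split transits at exponential-tail gaps, preferentially at
  high-rate positions (the Lee filter's global σ₀ is background-dominated
  at low-rate positions, suppressing splits there), which distorts profile
  shapes;
* every artifact ships a manifest (true transit counts, expected rates,
  seeds) sufficient to recompute expected statistics analytically; the
  tests assert generator statistics against these expectations within three
  standard errors.

What the generator does *not* emulate: diffusion during a transit
(flow-dominated regime, Péclet ≫ 1), optical point-spread-function detail
beyond an effective detection volume, detector dead time and afterpulsing,
photophysics (blinking/bleaching), and transverse position drift between
repeat scans. Passing recovery tests therefore demonstrate the analysis
chain's correctness under the stated transport-and-Poisson model, not
robustness to instrument non-idealities.

## Problem sizes used in the recovery studies

Sizing: truth {1, 3, 10, 30, 100} nm, ~5,000 counted molecules over 240
positions (dwell 2 s), three seeds per size, median asserted within 10%.
Deconvolution: 10⁴ bursts; coverage over 100 replicates at n_boot = 150.
Clusters: 500 events/crossing, 20 seeds, mean within 15%. Isotherm: eight
titration points, noiseless <1%, ten noisy replicates (σ = 0.05 nm) with
mean bias <10%. The reduced solver grid for these studies (45 radii,
101 × 9 cells) is cross-validated against finer grids by the interpolation
and slab-series tests.
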