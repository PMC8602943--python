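# Methods

## Model

The cell-intrinsic circuit couples NANOG (`N`), GATA6 (`G`) and secreted
FGF4 (`F`) per cell:

    dN/dt = λ ( α_N /(1 + G^β) + α_N,F /(1 + S^γ) − deg_N · N )
    dG/dt = λ ( α_G /(1 + N^η) − deg_G · G )
    dF/dt = λ ( α_F /(1 + G^δ) − deg_F · F )

where `S` is the sensed extracellular FGF4.  NANOG production is the sum
of a GATA6-repressed term (α_N = 2.5) and an FGF4-repressed term
(α_N,F = 0.5); GATA6 production is NANOG-repressed (α_G = 3); FGF4
production is GATA6-repressed (α_F = 3).  Hill coefficients β (GATA6 on
NANOG), γ (FGF4 on NANOG), η (NANOG on GATA6) and δ (GATA6 on FGF4) all
default to 2.  Degradation rates are 1; λ = 50 is a pure time-scaling
kinetic parameter (doubling λ doubles every right-hand side exactly).
The transcription of the three right-hand sides lives in a single
function (`model_core.transcribed_rhs`), with its analytic partial
derivatives kept alongside, so that any change of functional form is a
one-place edit.

This arrangement of the two NANOG production terms was selected among
the structurally admissible variants (NANOG repressed by GATA6 and by
FGF4, with the printed rate constants) as the one that jointly produces
the model's documented behaviors: the single cell is monostable
NANOG-high at zero FGF4 input, bistable around the mutant reference
input F_ext = 1.2 (so non-communicating populations inherit their
initial-condition bias), and monostable GATA6-high at high input (so the
external-dose response is sigmoidal and communication can force fate
transitions).  Variants in which FGF4 gates only a GATA6-repressed
sub-term leave both homogeneous population states stable and cannot
re-proportion a population started from a single fate.

### Sensing

`S_i` is the unweighted arithmetic mean of `F` over the neighborhood
(self excluded): all cells within two hops of the 4-connected lattice
graph, i.e. Manhattan distance ≤ 2 — 12 cells in the interior, fewer at
the no-flux boundaries, where the mean is taken over the actual
(truncated) neighborhood.  8-connectivity is a config switch.  Modes:
`mutant` replaces sensing by a constant `f_ext` (default 1.2);
`wildtype_plus_external` adds `f_ext_add` (default 1.0) to the
neighborhood mean.

### Stochastic integration

The SDE adds multiplicative noise `σ X dW` (σ = 0.1) per species and is
advanced with the Milstein scheme at Δt = 0.01:

    X ← X + f·Δt + σX·ΔW + ½σ²X·(ΔW² − Δt),  ΔW ~ N(0, Δt)

The update is clamped at zero: multiplicative noise preserves the origin
exactly, but a finite step can overshoot below zero; clamping was chosen
over rejection sampling for reproducibility.  The scheme's strong order
(~1, versus ~0.5 for Euler–Maruyama) is verified against the exact
geometric-Brownian-motion solution driven by the same Brownian path.
Cell heterogeneity draws every kinetic parameter of every cell from
Normal(base, 0.02), truncated at 0; Δt, σ and λ are integration/scale
constants shared by the population, not cell traits.

### Initial conditions and anchors

Populations are initialized from per-coordinate Gaussians with mean
μ_ics(p) = (1 − p)·μ_G−;N+ + p·μ_G+;N−, truncated at 0.  The anchors are
the two cell-states of the stable two-cell IHSS at the current
parameters ((2.618, 0.382, 2.618) and its mirror at defaults), computed
by the bifurcation module.  The Gaussian spread defaults to 0.05 state
units — small enough that the p = 0 and p = 1 clouds are unimodal and
well separated, large enough to populate both basins at p = 0.5; it is
config-exposed (`init_sd`).

### Phase duration and relaxation

One stochastic phase lasts `t_end` = 20 time units (2,000 steps).  With
λ = 50 the deterministic relaxation time is ~0.02 time units, so
population summaries are stationary well before the end of a phase
(summaries at t_end and t_end/2 agree to within the realization
scatter).  Deterministic relaxation integrates with σ = 0 until
max |rhs| < 1e−6 (or a t_max of 50, flagged if not converged); the
endpoint is insensitive to halving Δt.

### Division experiment

Starting from a 5×10 grid, five synchronous divisions along alternating
grid axes produce 10×10, 10×20, 20×20, 20×40 and 40×40 lattices (the
pre-division shape is chosen so the printed shape sequence emerges).
Each cycle runs a stochastic phase, doubles the grid (daughters adjacent
along the division axis, inheriting the mother's state and parameter set
exactly), relaxes deterministically, and snapshots.  Communication
conditions: `always`; `never` (mutant-mode sensing at the configured
f_ext throughout); and the hybrid `switch_off_after_cycle_k` (default
k = 3), which freezes each cell's sensed input at its value at the
switch — daughters inherit the frozen input.  The alternative reading of
the switch (jump to a constant external input) is available by running
`never` from a restart.

## Analyses

**Cell typing.** Simulated cells are typed by comparing N and G (exact
ties, a measure-zero event, are unassigned).  Measured two-channel
tables are fit with a two-component full-covariance Gaussian mixture
(scikit-learn, 5 seeded restarts, best likelihood kept); the component
with higher GATA6 mean is the GATA6+ type.  Cells are assigned when the
winning posterior exceeds 0.9, and outliers are removed per component at
Euclidean distance > 4 interquartile ranges of the component's
center-distance distribution (components with < 4 members skip the rule
with a warning; if all distances are equal the IQR is 0 and nothing is
flagged).  A log-transform flag (default off) covers intensity data
better described on a log scale.

**Neighbor graphs.** Delaunay edges are kept only when the segment
between the two cells passes through their shared Voronoi edge
(unbounded ridges are extended along the outward normal).  An exact
equivalent — the midpoint of the segment is strictly closer to the two
endpoints than to any other point — serves as the brute-force oracle in
the tests.  Duplicate or collinear inputs must be jittered (seeded,
±0.01 units).  Second neighbors are unlinked pairs sharing a first
neighbor.  Pooled first/second link distances are each fit with a 1-D
two-component mixture and the lower-mean component reported, separating
true neighbor distances from the heavy tail of erroneously kept links;
below 20 links per class the fit falls back to median/MAD.  Note that on
a near-regular square grid the trimming rule legitimately keeps roughly
half of the quad diagonals (their midpoints fall inside the tiny shared
Voronoi edge), so interior degrees average ~5, not exactly 4.

**Cluster radius.** Among GATA6+/NANOG+ cells only, and for every NANOG+
seed cell, the NANOG+ fraction within radius r is averaged over seeds
(the seed counts itself, so the raw fraction at r = 0 is exactly 1),
the global NANOG+ fraction is subtracted, and the result rescaled to 1
at r = 0.  The cluster radius is the first downward 0.5-crossing,
linearly interpolated; profiles that never cross are reported as
right-censored at the maximal radius.  The radius grid steps 1 µm for
imaging-like fields and one lattice spacing (= 1 cell diameter) for
simulation snapshots; because the seed's own contribution holds the
profile at 1 below the nearest-neighbor distance, sub-spacing radii are
produced by the interpolation between r = 0 and the first occupied
shell, and a finer grid would floor the statistic at ~0.8 cell
diameters instead.  Averaging per-seed fractions is the default; a
pooled-count variant sits behind a flag.  Field-of-view edge effects are
not corrected; the statistic quantifies feature length scales but
understates physical feature sizes.

**Neighborhood composition.** Fractions of each fate within a Euclidean
radius (default 31.7 µm, covering most first and second neighbors), self
excluded; cells with empty neighborhoods are excluded and counted.  The
random baseline permutes labels over fixed positions.

**Signaling-range fit.** Cells are binned by distance in half-open 3 µm
bins; the per-bin mean intensity is fit with a continuous
plateau-then-exponential model (baseline + amplitude, shared at the
kink) by weighted least squares (1/s.d.² where a bin has ≥ 2 cells,
unweighted otherwise), box constraints (lengths ≥ 0) and a multi-start
over candidate plateau positions.  Flat profiles are flagged as
non-converged rather than returning numbers.

## Synthetic data

Point patterns are jittered hexagonal packings (square optional) at a
target nearest-neighbor spacing (default 14 µm, jitter s.d. 4% of the
spacing) with random, block, disc or half-plane label models; expression
tables are bimodal two-component Gaussian mixtures with optional uniform
outliers; intensity profiles sample the plateau-decay model with
additive Gaussian noise.  Every generator is seeded and returns its
ground truth.  The generators emulate spacing statistics, bimodality and
decay shape — not cell shape, imaging noise structure, segmentation
errors or density gradients of real micrographs — so passing recovery
tests demonstrates correctness of the analysis chain, not performance on
real images.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale configurations chosen as
the package's own defaults: 10×10 grids with 10 realizations per
condition for proportioning sweeps (the full-scale reference is 100×100,
config-exposed), 20 realizations of the five-cycle division experiment
(reference 100), 150–200 multi-start roots for the two-cell analysis.
Fixed-point deduplication uses 1e−5 in state space; residual acceptance
1e−8; stability calls an eigenvalue real part beyond ±1e−8 decisive.
Branch tracking is dense multi-start root finding warm-started across
the grid rather than pseudo-arclength continuation — the 6-D system is
cheap and fold geometry is recovered by grid refinement; the shipped
branch-scan recipe scans a production rate (`alpha_g`) as its control
parameter.  A stable IHSS exists for alpha_g roughly in (2.4, 4.5) at
otherwise-default parameters.

## Known limitations

- No receptor/ERK mechanism, no FGF4 diffusion PDE, no cell motility,
  no asynchronous division or apoptosis, no physical cell geometry.
- The two-cell analysis does not continue limit cycles (no Hopf
  tracking) and the branch scan reports fold neighborhoods only to grid
  resolution.
- The mixture classifier assumes two populations; double-positive or
  double-negative subpopulations are absorbed as unassigned cells.
- Cluster radii depend on the radius grid below the nearest-neighbor
  spacing (see above); comparisons should use a common grid.
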