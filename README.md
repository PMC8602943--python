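# fatelattice

A lattice model of cell-type proportioning in the early mammalian
embryo-like (ICM/ESC) setting, together with the spatial and
classification analyses used to quantify it.  The package is aimed at
systems biologists studying how short-range paracrine FGF4 signaling
lets a population of embryonic stem cells split robustly into
epiblast-like (NANOG+) and primitive-endoderm-like (GATA6+) identities.

## The model

Each cell `i` on a rectangular grid carries three dimensionless species:
NANOG (`N`), GATA6 (`G`) and secreted FGF4 (`F`).  NANOG and GATA6
repress each other; GATA6 represses FGF4 production; and the FGF4 sensed
from the neighborhood represses NANOG production:

    dN_i/dt = λ ( α_N /(1 + G_i^β) + α_N,F /(1 + F_ext,i^γ) − N_i )
    dG_i/dt = λ ( α_G /(1 + N_i^η) − G_i )
    dF_i/dt = λ ( α_F /(1 + G_i^δ) − F_i )
    F_ext,i = mean of F_j over the neighborhood N(i)

with α_N = 2.5, α_N,F = 0.5, α_G = α_F = 3, all Hill coefficients 2,
degradation rates 1 and λ = 50 as time-scaling kinetic parameter.  The
neighborhood is every cell within two lattice hops (12 cells in the
interior; no-flux boundaries).  A stochastic version adds multiplicative
noise `σ X dW` (σ = 0.1) and is integrated with the Milstein scheme at
Δt = 0.01; cell-to-cell heterogeneity perturbs every kinetic parameter
independently (s.d. 0.02).  Three communication modes are supported:
wild-type (neighborhood sensing), mutant (no communication, constant
external input `F_ext`, default 1.2), and wild-type plus an additive
external input (default 1.0).

The coupled system supports an *inhomogeneous steady state* (IHSS): a
stable fixed point in which communicating cells occupy mutually
exclusive NANOG-high / GATA6-high states.  For the two-cell system at
default parameters the IHSS cell-states are (N, G, F) ≈ (2.618, 0.382,
2.618) and (0.382, 2.618, 0.382); these also serve as the anchor states
of the initial-condition construction μ_ics(p) = (1 − p)·μ_G−;N+ +
p·μ_G+;N−.

On top of the simulator the package implements the analyses applied to
imaging and flow-cytometry-like data: a two-component Gaussian-mixture
cell-type classifier with posterior threshold 0.9 and a 4×IQR outlier
rule; trimmed-Delaunay neighbor graphs with first/second-neighbor
distance statistics; neighborhood composition within a fixed radius; the
scaled-fraction cluster-radius statistic (the distance at which the
scaled NANOG+ fraction around NANOG+ cells drops to 0.5); and the
plateau-plus-one-phase-exponential-decay fit for signaling-range
profiles binned at 3 µm.  Synthetic generators emulate each input class
so every stage has a closed generate → analyze → recover loop.

## Worked example

Run the five-cycle cell-division experiment (10×10 → 40×40 grids) with
and without communication and summarize NANOG+ cluster radii:

```python
from fatelattice.pipeline import recipe_divisions, division_summary
from fatelattice.simulator import SimulationConfig

cfg = SimulationConfig(init_p=0.5, seed=1)
df = recipe_divisions(cfg, comms=("always", "never"), n_realizations=3, seed=1)
print(division_summary(df)[["comm", "cycle", "median"]])
```

```
     comm  cycle    median
0  always      1  0.702905
1  always      2  0.837235
2  always      3  0.824628
3  always      4  0.845789
4  always      5  0.910963
5   never      1  0.918367
6   never      2  1.479787
7   never      3  2.114842
8   never      4  3.089780
9   never      5  4.152669
```

Radii are in cell diameters (one lattice spacing).  With continuous
communication the median cluster radius stays nearly constant (~0.7 →
~0.9 over five divisions): short-range signaling re-proportions fates
after every division and keeps the pattern locally mixed.  Without
communication, fates propagate clonally and clusters grow with every
division, ending more than four times larger.

The same experiments are available from the shell:

```bash
fatelattice divisions --realizations 20 --seed 1 --out divisions.csv
fatelattice sweep-p --realizations 10 --seed 1 --out proportioning.csv
fatelattice bifurcate --param alpha_g --lo 1 --hi 4 --out branches.csv
```

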