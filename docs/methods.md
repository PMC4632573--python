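# Methods

## Model

`reefresilience` simulates a metapopulation of `n` reef sub-populations
(default 114), each with biomass `X_i` scaled to its carrying capacity, on a
directed dispersal network. Local dynamics are logistic with growth rate
`r` (per unit time, default 0.2 — a value typical of a medium-lived reef
fish); a fraction of each patch's production migrates:

    dX_i/dt = r_i X_i (1 - X_i) - s r_i X_i + I_i(X)

`s` in [0, 1] is the connection quality (migrant survivorship): `s = 0`
decouples the patches, `s = 1` routes all production through the network.
The immigration term `I_i` is a modelling choice (the *closure*), discussed
below.

Connectivity follows an exponential distance-decay kernel: the ordered pair
`j -> i` at Euclidean distance `D` carries base weight `w = exp(-a D - b)`
with `a = 3.4`, `b = 3.91` (fitted elsewhere to hydrodynamic transport data
and taken as given constants), retained only when `w > 0.01` strictly. The
threshold implies a hard cutoff distance `(ln 100 - b)/a ≈ 0.2045` model
units. Link counts are always reported as ordered pairs; weights are
symmetric, so every retained unordered pair appears twice. Self-links are
excluded even though `w(0) = e^{-3.91} ≈ 0.02` clears the threshold:
migration from a reef to itself is meaningless here. At the reference size
(114 nodes at the calibrated density) the network carries 3904 directed
links, i.e. a mean out-degree near 34. Connection quantity `alpha` is the
number of directed links kept from this full set, drawn uniformly without
replacement per replicate.

## Immigration closures

The distribution of emigrants among destinations admits several readings;
all three are implemented behind `ModelParams.migration_mode`:

* **conservative** (default). Each source with at least one selected
  out-link exports `s r X` and the outflow is split over its out-links in
  proportion to base weights. Total immigration equals total emigration
  identically (checked to 1e-10 in the tests). A node with no selected
  out-link keeps its production — there is nowhere for it to go — and a
  node with no in-links receives nothing.
* **pool**. All exports enter a common pool redistributed over
  destinations in proportion to their weighted supply `sum_j w_ji X_j`.
  Also mass-conserving, but destinations compete globally rather than
  per-source.
* **literal**. `I_i = k_i * X~` with `k_i = sum_j L_ji X_j / sum_j L_ji`
  and `X~ = sum_i r_i X_i`. Because every `k_i` is order 1 while `X~` is
  order `r n`, immigration exceeds emigration roughly `n`-fold: at `n=114`
  the integrator overflows within one time unit. The closure is retained
  for transparency; the package raises a descriptive error rather than
  integrating garbage.

The conservative closure is the documented default on two grounds: it is
the only reading that is simultaneously dimensionally consistent at any
`n` and compatible with the decoupled `s = 0` limit, and in calibration
runs (2000 replicates, base scenario) it reproduces the reference
full-migration recovery time more closely than the pool closure (≈27.1 vs
≈28.7 time steps against a reference of 25.8).

Note one consequence of any mass-conserving closure: a disturbed patch's
low-density growth rate is `r (1 - s)`, because the emigration term removes
`s r X` even when `X` is small. At high `s` and very low `alpha` (so that
return flow is scarce) recovery therefore *slows* as quality rises, and at
`s = 1` some poorly connected patches equilibrate at `X = 0`. This is real
model behaviour, not a bug; it breaks the intuition that more quality is
always better precisely at the sparse edge of the connection budget (see
"Known limitations").

## Simulation protocol

One replicate: (1) draw `alpha` directed links uniformly without
replacement; (2) relax the system from `X = 1` to its equilibrium (the
pre-disturbance baseline; for `s = 0` the two coincide); (3) draw a
disturbance centre uniformly on the bounding box of the nodes, redrawing
until at least one node is hit (switchable; a miss would register as a
zero-length "recovery"); (4) remove 99% (configurable) of the biomass of
every node within 0.4 model units of the centre, boundary inclusive;
(5) integrate and record the recovery time — the first unit-time
checkpoint at which aggregate biomass over *all* nodes regains 95% of its
pre-disturbance value. Replicates that never recover within the horizon
(`t_max = 500`) are censored, excluded from means and counted separately;
at default settings censoring does not occur.

Integration is classical fixed-step 4th-order Runge–Kutta, `dt = 0.05`
(the step is snapped to an integer number per unit interval), biomass
clipped at zero after each step. Against the logistic closed form the
trajectory is accurate to <1e-6 per checkpoint, and the scheme shows its
4th-order convergence (~16x error drop per step halving). "Time steps" in
reported recovery times are unit time intervals, not integrator steps —
the `1/r` scaling of the decoupled model fixes this interpretation (a
single patch recovering from 1% at `r = 0.2` crosses 95% at `t = 37.70`,
reported as 38).

Equilibrium burn-in integrates with a coarser stride (`relax_dt = 0.5`;
the fixed point does not depend on the step) until the residual
`max|dX/dt|` falls below 1e-9. Nodes collapsing onto the `X = 0` boundary
approach it algebraically (`~1/t`), which time-stepping cannot finish in
reasonable time; in the conservative mode — whose immigration is linear in
`X`, making the Jacobian exact and cheap — burn-in therefore switches to a
projected Newton solve once the residual reaches 1e-4, pinning converged
boundary nodes. Pure integration remains available
(`relax_to_equilibrium(..., method="integrate")`) and agrees with the
hybrid to <1e-8 on well-coupled networks.

Randomness is seeded hierarchically: replicate `k` of grid cell `c` under
base seed `B` uses `SeedSequence([B, c, k])`, so any cell can be recomputed
in isolation and full reruns are bit-identical.

## Synthetic reef strip

The node generator emulates an elongated fringing-reef habitat: an
alongshore strip (long axis = `y`, the latitude proxy used by the
growth-gradient scenarios) of default aspect 0.1 x 1.3. The default layout
is *clustered* — 12 cluster centres strung along the strip with Gaussian
node scatter (sd 0.05) — because reef habitat is patchy, and patchiness is
what gives the disturbance-severity distribution its spread: with a
uniform strip the between-replicate SD of decoupled recovery times is
~1.3 steps, versus ~2.2 for the clustered layout and ~2.4 in the reference
system. A uniform layout is available, with the strip length solved so the
expected link count matches the target mean out-degree.

After placement the coordinates are rescaled by a single factor chosen so
the link rule retains exactly `round(n * 3904/114)` directed links (the
scale slides the cutoff through the sorted pairwise distances). The draw
is repeated, deterministically under the seed, until the network is
connected. What the generator does *not* emulate: the true shoreline
curvature, real inter-reef distances, and any anisotropy of larval
transport. Quantities that depend on the disturbance-footprint statistics
(notably the absolute recovery means) transfer to within about one time
step; per-geometry idiosyncrasies (e.g. the exact quality level needed at
a given connection cap) should be recomputed on real coordinates.

## Sensitivity scenarios

The scenario suite reruns the disturbance experiment on the full link set
under: base parameters; `r = 0.25` and `r = 0.15`; 50% instead of 99%
removal; no spatial effect on migration (every ordered pair connected with
weight 1); twice the spatial effect (weights recomputed with slope 6.8 on
the *same* link pairs — the suite holds the connection count fixed, and
re-thresholding at the doubled slope would drop three quarters of the
links); and latitude-linked growth gradients `r_i = 0.2 + g (y_i - mean y)`
with `g` scaled so `max|r_i - 0.2| = 0.05`, increasing northward or
southward. The gradient magnitude is a free parameter: the natural
per-degree-latitude scaling depends on the coordinate units of the node
file, so gradient scenarios are qualitative.

## Iso-resilience surface and offsets

Mean recovery times on the 11 x 10 grid (`s` in 0..1, `alpha` in
200..3904) are interpolated bilinearly; the interpolant reproduces cell
means exactly at grid nodes. Because cell means are Monte-Carlo noisy, an
optional smoothing pass projects the grid onto surfaces non-increasing in
both axes (alternating row/column pool-adjacent-violators sweeps to a
near-fixed-point — approximately, not exactly, the least-squares bimonotone
fit). Iso-resilience contours are extracted by marching squares.

Two planning problems are solved on the fitted surface under a linear
budget `c_s s + c_alpha alpha <= B`: the fastest attainable recovery for a
given budget (dense grid search plus SLSQP refinement; ties broken toward
lower cost, then lower `s`), and the minimum budget that restores a target
recovery time under a cap on `alpha` (per-`alpha` bisection on the
smallest feasible `s`, then a sweep over `alpha`). The unit costs and
budget have no defaults — they are policy inputs. `alpha` is treated as
continuous inside the optimizers and rounded to whole links for reporting
(grid spacing is ~400 links, so the rounding is immaterial).

## Known limitations

* The monotone "more is better" reading of the indifference map holds on
  the bulk of the surface but fails on the sparsest column
  (`alpha = 200`): under mass-conserving migration, high quality with
  almost no links slows recovery (see the closure discussion). Iso-contour
  nestedness and the offset logic are therefore most meaningful for
  `alpha` above a few links per node.
* Demographic/environmental stochasticity, age structure and harvest are
  out of scope; disturbance is a single instantaneous event.
* The decay coefficients 3.4 and 3.91 are taken as given; refitting them
  requires hydrodynamic data outside the package's scope.
* Reported acceptance figures use 2000 replicates per scenario and 1000
  (tests) or 300 (acceptance script) replicates per grid cell — sizes at
  which Monte-Carlo standard errors (~0.05–0.8 time steps) are small
  against the tolerances of interest.
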