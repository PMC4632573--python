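# reefresilience

Metapopulation resilience on dispersal networks, and the cost of keeping it.

`reefresilience` is a simulation and decision-support tool for conservation
planning on spatially structured populations — the motivating system is a
reef fish metapopulation spread over ~114 reef patches along an elongated
fringing reef. It answers two questions:

1. **How fast does the whole metapopulation bounce back from a localized
   disturbance** (Pimm resilience, measured as recovery time), as a function
   of the *quantity* (α, number of dispersal links) and *quality* (s,
   migrant survivorship) of its connections?
2. **What is the cheapest way to preserve that recovery speed** when human
   activity permanently removes connections — i.e. the minimum environmental
   offset, in budget terms, that trades quality for lost quantity along an
   iso-resilience (indifference) curve?

## Model

Each sub-population `i` carries biomass `X_i` scaled to carrying capacity:

    dX_i/dt = r_i X_i (1 - X_i) - s r_i X_i + I_i(X)

with logistic growth (`r = 0.2` per unit time by default), emigration of the
fraction `s ∈ [0, 1]` of local production, and immigration `I_i` routed over
a directed dispersal network whose link weights decay exponentially with
inter-reef distance, `w = exp(-3.4 D - 3.91)`, thresholded at `w > 0.01`
(cutoff distance ≈ 0.204 model units; 3904 directed links at the reference
size). By default immigration is mass-conserving: each source's outflow is
split over its out-links by weight. Trajectories are integrated with
fixed-step RK4; recovery time is the first unit-time checkpoint at which
aggregate biomass regains 95% of its pre-disturbance equilibrium after 99%
of the biomass within 0.4 units of a random point is removed. Monte-Carlo
replicates sweep an 11 × 10 grid of (s, α); the resulting mean-recovery
surface yields iso-resilience contours and linear-budget optimisation.
See `docs/methods.md` for assumptions, closures, numerical choices and
limitations.

## Worked example

```python
import reefresilience as rr

# a 114-node synthetic reef strip carrying exactly 3904 directed links
net = rr.ReefNetwork.synthetic(114, rng=0)
print(net.report())
# {'n_nodes': 114, 'n_links': 3904, 'mean_out_degree': 34.2456...,
#  'min_out_degree': 6, 'max_out_degree': 46,
#  'cutoff_distance': 0.2044618...}

# one disturbance replicate at full connectivity
res = rr.run_replicate(net, alpha=3904, params=rr.ModelParams(s=1.0), rng=5)
print(res.recovery_time, res.n_disturbed)
# 22 23   -> 23 of 114 reefs disturbed; the aggregate regained 95% of its
#            equilibrium biomass 22 time steps later

# the sensitivity suite (means +- sd of recovery time, 2000 replicates)
table = rr.run_scenarios(net, n_reps=2000, base_seed=101)
print(table[table.scenario == "base case"])
#     scenario    s    mean       sd     n  n_censored
#    base case  1.0  27.286  2.90765  2000           0
#    base case  0.0  34.087  2.62486  2000           0
# -> migration at full quality buys ~7 time steps of recovery speed
```

From a simulated `(s, α)` surface, the offset problem — how much connection
quality must rise to hold recovery time when connections are capped:

```python
surf = rr.run_grid(net, n_reps=300, base_seed=11)     # 11 x 10 sweep
model = rr.fit_surface(surf, smoothing=True)
target = float(model(0.12, 3904))                     # pre-impact resilience
sol = rr.min_budget_for_target(model, target, alpha_cap=800,
                               c_s=1.0, c_alpha=1e-4)
print(round(target, 1), round(sol.s, 2))
# 32.0 0.32  -> capped at 800 links, quality must rise from 0.12 to ~0.32
#               to keep the same mean recovery time
```

The same pipelines are exposed on the command line
(`reefresilience synth | network | simulate | grid | scenarios | offset`);
every output CSV embeds a provenance header (version, seed, full config)
from which it can be regenerated.

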