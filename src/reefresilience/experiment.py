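"""Monte-Carlo disturbance experiments and the recovery-time statistic.

Recovery time (Pimm resilience) is the number of unit time steps for the
aggregate biomass of the entire metapopulation — disturbed and undisturbed
nodes together — to regain 95% of its pre-disturbance value.  One
replicate: draw a random subset of alpha links, relax to the
pre-disturbance equilibrium, draw a spatially random disturbance, remove
biomass, integrate forward and score.  Replicates are seeded
hierarchically from (base seed, cell index, replicate index) so that every
grid cell is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import disturbance as _dist
from .dynamics import (CompiledNetwork, ModelParams, Trajectory,
                       _integrate_until, _kernel_args, _steps_per_unit,
                       compile_network, integrate, relax_to_equilibrium)
from .network import LinkSet, ReefNetwork, complete_links, sample_links

#: sentinel recovery time of a replicate that never recovered in-horizon
CENSORED = -1
#: aggregate-recovery threshold as a fraction of the initial state
RECOVERY_THRESHOLD = 0.95


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one disturbance replicate."""

    recovery_time: int                 # unit time steps; CENSORED if never
    censored: bool
    n_disturbed: int
    initial_aggregate: float
    post_disturbance_aggregate: float
    seed: int | None = None
    event: _dist.DisturbanceEvent | None = None


def recovery_time(trajectory: Trajectory, initial_aggregate: float,
                  threshold: float = RECOVERY_THRESHOLD) -> RecoveryResult:
    """Score a recorded trajectory: first checkpoint at or above threshold.

    Checkpoint 0 is the immediate post-disturbance state, so a replicate
    whose disturbance barely dents the aggregate scores 0.
    """
    agg = trajectory.aggregate
    if agg.size == 0:
        raise ValueError("empty trajectory")
    target = threshold * initial_aggregate
    hits = np.nonzero(agg >= target)[0]
    n_dist = (int(trajectory.disturbed_mask.sum())
              if trajectory.disturbed_mask is not None else 0)
    if hits.size == 0:
        return RecoveryResult(CENSORED, True, n_dist, initial_aggregate,
                              float(agg[0]))
    return RecoveryResult(int(trajectory.times[hits[0]]), False, n_dist,
                          initial_aggregate, float(agg[0]))


def _fast_recovery(post_state: np.ndarray, net: CompiledNetwork,
                   params: ModelParams, initial_aggregate: float,
                   threshold: float) -> tuple[int, bool]:
    """Integrate until the aggregate recovers, without recording states."""
    steps, dt = _steps_per_unit(params.dt)
    t = _integrate_until(post_state.copy(), threshold * initial_aggregate,
                         int(np.ceil(params.t_max)), steps, dt,
                         *_kernel_args(net, params))
    if t <= -2:
        raise FloatingPointError(
            f"non-finite state at t={-(t + 2)} under migration mode "
            f"{params.migration_mode!r} (s={params.s})")
    return (CENSORED, True) if t == CENSORED else (int(t), False)


def run_replicate(network: ReefNetwork, alpha: int, params: ModelParams,
                  rng: int | np.random.SeedSequence | None = 0,
                  radius: float = _dist.DEFAULT_RADIUS,
                  removal_fraction: float = _dist.DEFAULT_REMOVAL,
                  require_hit: bool = True,
                  threshold: float = RECOVERY_THRESHOLD,
                  return_trajectory: bool = False,
                  _compiled: CompiledNetwork | None = None,
                  _equilibrium: np.ndarray | None = None):
    """One full replicate: subsample links, relax, disturb, integrate, score.

    Fully reproducible from ``(rng, config)``.  ``_compiled`` and
    ``_equilibrium`` allow scenario sweeps over the full link set to reuse
    the burn-in across replicates (the equilibrium depends only on the
    network and parameters, not on the disturbance draw).
    """
    ss = (rng if isinstance(rng, np.random.SeedSequence)
          else np.random.SeedSequence(rng))
    seed_links, seed_event = ss.spawn(2)
    if _compiled is None:
        if alpha == len(network.links):
            net = compile_network(network.links)
        else:
            subset = sample_links(network.links, alpha,
                                  np.random.default_rng(seed_links))
            net = compile_network(subset)
    else:
        net = _compiled
    eq = (relax_to_equilibrium(net, params) if _equilibrium is None
          else _equilibrium)
    event = _dist.sample_event(network.nodes, radius, removal_fraction,
                               np.random.default_rng(seed_event),
                               require_hit=require_hit)
    mask = _dist.disturbed_set(event, network.nodes)
    post = _dist.apply_event(eq, mask, removal_fraction)
    initial_aggregate = float(eq.sum())
    if return_trajectory:
        traj = integrate(post, net, params, disturbed_mask=mask)
        res = recovery_time(traj, initial_aggregate, threshold)
        res = replace(res, seed=_entropy_int(ss), event=event)
        return res, traj
    rt, censored = _fast_recovery(post, net, params, initial_aggregate,
                                  threshold)
    return RecoveryResult(rt, censored, int(mask.sum()), initial_aggregate,
                          float(post.sum()), _entropy_int(ss), event)


def _entropy_int(ss: np.random.SeedSequence) -> int | None:
    ent = ss.entropy
    return int(ent) if np.isscalar(ent) else None


def _log_row(sink: list | None, scenario: str, s: float, alpha: int,
             rep: int, res: RecoveryResult) -> None:
    """Append one replicate/event record to a results log."""
    if sink is None:
        return
    ev = res.event
    sink.append({
        "scenario": scenario, "s": s, "alpha": alpha, "replicate": rep,
        "seed": res.seed, "n_disturbed": res.n_disturbed,
        "recovery_time": res.recovery_time, "censored": int(res.censored),
        "centre_x": ev.centre[0] if ev else np.nan,
        "centre_y": ev.centre[1] if ev else np.nan,
        "radius": ev.radius if ev else np.nan,
        "removal_fraction": ev.removal_fraction if ev else np.nan,
        "redraws": ev.n_redraws if ev else 0,
    })


# ---------------------------------------------------------------------------
# (s, alpha) grid sweep
# ---------------------------------------------------------------------------

def default_s_grid(n: int = 11) -> np.ndarray:
    """n connection-quality values evenly spaced on [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def default_alpha_grid(n_links: int, n: int = 10,
                       alpha_min: int = 200) -> np.ndarray:
    """n link counts evenly spaced from alpha_min to the full network."""
    return np.round(np.linspace(alpha_min, n_links, n)).astype(int)


@dataclass(frozen=True)
class ResilienceSurface:
    """Mean +- SD recovery time on the (s, alpha) grid."""

    s_grid: np.ndarray
    alpha_grid: np.ndarray
    mean: np.ndarray        # (n_s, n_alpha); NaN where all reps censored
    sd: np.ndarray
    n_reps: np.ndarray
    n_censored: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.s_grid):
            for j, a in enumerate(self.alpha_grid):
                rows.append((s, int(a), self.mean[i, j], self.sd[i, j],
                             int(self.n_reps[i, j]),
                             int(self.n_censored[i, j])))
        return pd.DataFrame(rows, columns=["s", "alpha", "mean", "sd", "n",
                                           "n_censored"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResilienceSurface":
        s_grid = np.sort(df["s"].unique())
        a_grid = np.sort(df["alpha"].unique())
        shape = (s_grid.size, a_grid.size)
        mean = np.full(shape, np.nan)
        sd = np.full(shape, np.nan)
        n = np.zeros(shape, dtype=int)
        nc = np.zeros(shape, dtype=int)
        si = {v: i for i, v in enumerate(s_grid)}
        ai = {v: j for j, v in enumerate(a_grid)}
        for _, row in df.iterrows():
            i, j = si[row["s"]], ai[row["alpha"]]
            mean[i, j] = row["mean"]
            sd[i, j] = row["sd"]
            n[i, j] = row.get("n", 0)
            nc[i, j] = row.get("n_censored", 0)
        return cls(s_grid, a_grid, mean, sd, n, nc)


def run_grid(network: ReefNetwork,
             s_values: np.ndarray | None = None,
             alpha_values: np.ndarray | None = None,
             n_reps: int = 100,
             base_seed: int = 0,
             params: ModelParams | None = None,
             radius: float = _dist.DEFAULT_RADIUS,
             removal_fraction: float = _dist.DEFAULT_REMOVAL,
             require_hit: bool = True,
             progress: bool = False,
             replicate_log: list | None = None) -> ResilienceSurface:
    """Monte-Carlo sweep over the (s, alpha) grid.

    Each cell runs ``n_reps`` replicates seeded from
    ``(base_seed, cell_index, replicate_index)``; a rerun with the same
    base seed is bit-identical, and any cell can be recomputed in
    isolation.  Censored replicates are excluded from mean/SD and counted.
    Pass a list as ``replicate_log`` to collect per-replicate records
    (recovery time, disturbance centre, redraw count, ...).
    """
    base = params or ModelParams()
    s_values = default_s_grid() if s_values is None else np.asarray(s_values)
    if alpha_values is None:
        alpha_values = default_alpha_grid(len(network.links))
    alpha_values = np.asarray(alpha_values, dtype=int)
    shape = (s_values.size, alpha_values.size)
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    nrep = np.zeros(shape, dtype=int)
    ncen = np.zeros(shape, dtype=int)
    cells = [(i, j) for i in range(s_values.size)
             for j in range(alpha_values.size)]
    iterator = cells
    if progress:
        from tqdm import tqdm
        iterator = tqdm(cells, desc="grid cells")
    for (i, j) in iterator:
        cell_index = i * alpha_values.size + j
        p = replace(base, s=float(s_values[i]))
        times = np.empty(n_reps)
        cen = 0
        for rep in range(n_reps):
            ss = np.random.SeedSequence([base_seed, cell_index, rep])
            res = run_replicate(network, int(alpha_values[j]), p, ss,
                                radius=radius,
                                removal_fraction=removal_fraction,
                                require_hit=require_hit)
            _log_row(replicate_log, "grid", float(s_values[i]),
                     int(alpha_values[j]), rep, res)
            if res.censored:
                cen += 1
                times[rep] = np.nan
            else:
                times[rep] = res.recovery_time
        ok = ~np.isnan(times)
        nrep[i, j] = n_reps
        ncen[i, j] = cen
        if ok.any():
            mean[i, j] = times[ok].mean()
            sd[i, j] = times[ok].std(ddof=1) if ok.sum() > 1 else 0.0
    return ResilienceSurface(s_values, alpha_values, mean, sd, nrep, ncen)


# ---------------------------------------------------------------------------
# sensitivity scenario suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One sensitivity scenario run on the full link set.

    ``r_spec`` is ``("constant", value)`` or ``("north"|"south", magnitude)``
    for a latitude-linked growth gradient: ``r_i = r0 + g * (y_i - mean y)``
    with ``g`` scaled so ``max|r_i - r0|`` equals the magnitude, increasing
    northward (+y) or southward (-y).  ``link_rule`` is ``"default"``,
    ``"uniform"`` (every pair connected with weight 1, i.e. no spatial
    effect on migration) or ``"double_decay"`` (decay slope doubled,
    i.e. twice the spatial effect).
    """

    name: str
    r_spec: tuple[str, float] = ("constant", 0.2)
    removal_fraction: float = _dist.DEFAULT_REMOVAL
    link_rule: str = "default"

    def materialize(self, network: ReefNetwork,
                    base: ModelParams) -> tuple[LinkSet, ModelParams]:
        kind, value = self.r_spec
        if kind == "constant":
            r = float(value)
        elif kind in ("north", "south"):
            y = network.nodes.y
            dev = y - y.mean()
            span = np.abs(dev).max()
            if span == 0:
                raise ValueError("degenerate geometry: no latitude spread")
            g = value / span * (1.0 if kind == "north" else -1.0)
            r = 0.2 + g * dev
            if np.any(r <= 0):
                raise ValueError("gradient too steep: non-positive growth rate")
        else:
            raise ValueError(f"unknown r spec kind {kind!r}")
        if self.link_rule == "default":
            links = network.links
        elif self.link_rule == "uniform":
            links = complete_links(network.n)
        elif self.link_rule == "double_decay":
            # Same link pairs as the base network (the sensitivity table
            # holds the connection count fixed); weights recomputed with a
            # doubled decay slope, i.e. steeper localization of migration.
            L = network.links
            d = network.distances[L.src, L.dst]
            links = LinkSet(L.src, L.dst, np.exp(-2 * L.a * d - L.b),
                            L.n_nodes, a=2 * L.a, b=L.b, threshold=0.0)
        else:
            raise ValueError(f"unknown link rule {self.link_rule!r}")
        return links, replace(base, r=r)


def default_scenario_suite() -> list[ScenarioSpec]:
    """The sensitivity suite: growth rate, disturbance severity, spatial
    structure of migration, and latitudinal growth gradients."""
    return [
        ScenarioSpec("base case"),
        ScenarioSpec("r=0.25", r_spec=("constant", 0.25)),
        ScenarioSpec("r=0.15", r_spec=("constant", 0.15)),
        ScenarioSpec("disturbance=50%", removal_fraction=0.5),
        ScenarioSpec("no spatial effect", link_rule="uniform"),
        ScenarioSpec("twice spatial effect", link_rule="double_decay"),
        ScenarioSpec("r northerly increase", r_spec=("north", 0.05)),
        ScenarioSpec("r southerly increase", r_spec=("south", 0.05)),
    ]


def run_scenarios(network: ReefNetwork,
                  suite: list[ScenarioSpec] | None = None,
                  n_reps: int = 1000,
                  base_seed: int = 0,
                  s_values: tuple[float, ...] = (1.0, 0.0),
                  params: ModelParams | None = None,
                  radius: float = _dist.DEFAULT_RADIUS,
                  require_hit: bool = True,
                  threshold: float = RECOVERY_THRESHOLD,
                  progress: bool = False,
                  replicate_log: list | None = None) -> pd.DataFrame:
    """Run each scenario at each connection quality on the full link set.

    The equilibrium burn-in is computed once per (scenario, s) and shared
    across replicates, which is exact because scenarios never subsample
    links.  Returns a tidy frame: scenario, s, mean, sd, n, n_censored.
    """
    if not suite:
        suite = default_scenario_suite()
    if len({sc.name for sc in suite}) != len(suite):
        raise ValueError("scenario names must be unique within a suite")
    base = params or ModelParams()
    rows = []
    combos = [(k, sc, si, s) for k, sc in enumerate(suite)
              for si, s in enumerate(s_values)]
    if progress:
        from tqdm import tqdm
        combos = tqdm(combos, desc="scenarios")
    for k, sc, si, s in combos:
        links, p = sc.materialize(network, base)
        p = replace(p, s=float(s))
        net = compile_network(links)
        eq = relax_to_equilibrium(net, p)
        initial_aggregate = float(eq.sum())
        times = np.empty(n_reps)
        cen = 0
        for rep in range(n_reps):
            ss = np.random.SeedSequence([base_seed, k, si, rep])
            _, seed_event = ss.spawn(2)
            event = _dist.sample_event(network.nodes, radius,
                                       sc.removal_fraction,
                                       np.random.default_rng(seed_event),
                                       require_hit=require_hit)
            mask = _dist.disturbed_set(event, network.nodes)
            post = _dist.apply_event(eq, mask, sc.removal_fraction)
            rt, censored = _fast_recovery(post, net, p, initial_aggregate,
                                          threshold)
            if replicate_log is not None:
                _log_row(replicate_log, sc.name, float(s), len(links), rep,
                         RecoveryResult(rt, censored, int(mask.sum()),
                                        initial_aggregate,
                                        float(post.sum()),
                                        _entropy_int(ss), event))
            if censored:
                cen += 1
                times[rep] = np.nan
            else:
                times[rep] = rt
        ok = ~np.isnan(times)
        rows.append({
            "scenario": sc.name, "s": float(s),
            "mean": times[ok].mean() if ok.any() else np.nan,
            "sd": times[ok].std(ddof=1) if ok.sum() > 1 else 0.0,
            "n": n_reps, "n_censored": cen,
        })
    return pd.DataFrame(rows)


def summarize_trajectories(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Group mean +- SD time series for disturbed vs undisturbed nodes.

    For each replicate the per-checkpoint mean biomass of each group is
    taken; means and SDs are then computed across replicates.  Trajectories
    are truncated to the shortest horizon present.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    T = min(t.X.shape[0] for t in trajectories)
    out = {"time": np.arange(T)}
    for label, member in (("disturbed", True), ("undisturbed", False)):
        series = []
        for traj in trajectories:
            if traj.disturbed_mask is None:
                raise ValueError("trajectory lacks a disturbed-node mask")
            sel = traj.disturbed_mask == member
            if sel.any():
                series.append(traj.X[:T, sel].mean(axis=1))
        if not series:
            warnings.warn(f"no {label} nodes in any trajectory")
            out[f"{label}_mean"] = np.full(T, np.nan)
            out[f"{label}_sd"] = np.full(T, np.nan)
            continue
        arr = np.vstack(series)
        out[f"{label}_mean"] = arr.mean(axis=0)
        out[f"{label}_sd"] = (arr.std(axis=0, ddof=1) if arr.shape[0] > 1
                              else np.zeros(T))
    return pd.DataFrame(out)
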