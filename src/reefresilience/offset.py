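"""Iso-resilience curves and budget-constrained conservation offsets.

The simulated mean recovery time on the (s, alpha) grid is interpolated
into a response surface T(s, alpha).  Level sets of T are iso-resilience
(indifference) curves: combinations of connection quality and quantity
with equal recovery time.  A linear conservation budget
``c_s * s + c_alpha * alpha <= B`` defines affordable combinations; two
planning problems are solved on the surface:

* best attainable resilience (minimum recovery time) under a budget — at
  the tangency of the budget line with the furthest iso-resilience curve
  when T is strictly decreasing in both controls;
* minimum budget to restore a target recovery time when the number of
  connections is capped (the environmental-offset problem: quality bought
  to compensate lost quantity).

Monte-Carlo cell means are noisy, so an optional isotone smoothing pass
projects the grid onto surfaces non-increasing in both axes before
interpolating; the unsmoothed bilinear interpolant reproduces cell means
exactly at grid nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq, minimize
from skimage import measure as _measure

from .experiment import ResilienceSurface


def _isotone_decreasing(values: np.ndarray) -> np.ndarray:
    """PAVA projection onto non-increasing sequences (least squares)."""
    from sklearn.isotonic import isotonic_regression
    return isotonic_regression(values, increasing=False)


def monotone_smooth(grid: np.ndarray, n_sweeps: int = 50,
                    tol: float = 1e-10) -> np.ndarray:
    """Alternating row/column isotone projections until (near) fixed point.

    Enforces mean recovery time non-increasing in s (axis 0) and in alpha
    (axis 1).  Alternating projections converge to a surface monotone in
    both axes; the result is near the least-squares bimonotone fit though
    not exactly it (documented approximation).
    """
    Z = grid.astype(float).copy()
    for _ in range(n_sweeps):
        prev = Z.copy()
        for i in range(Z.shape[0]):
            Z[i, :] = _isotone_decreasing(Z[i, :])
        for j in range(Z.shape[1]):
            Z[:, j] = _isotone_decreasing(Z[:, j])
        if np.max(np.abs(Z - prev)) < tol:
            break
    return Z


@dataclass(frozen=True)
class SurfaceModel:
    """Bilinear interpolant of the resilience surface over the grid hull."""

    s_grid: np.ndarray
    alpha_grid: np.ndarray
    values: np.ndarray          # (n_s, n_alpha), possibly smoothed
    smoothed: bool

    def __post_init__(self):
        interp = RegularGridInterpolator(
            (self.s_grid, self.alpha_grid.astype(float)), self.values,
            method="linear", bounds_error=True)
        object.__setattr__(self, "_interp", interp)

    def __call__(self, s, alpha):
        s_arr, a_arr = np.broadcast_arrays(np.asarray(s, dtype=float),
                                           np.asarray(alpha, dtype=float))
        out = self._interp(np.column_stack([s_arr.ravel(), a_arr.ravel()]))
        return out.reshape(s_arr.shape) if s_arr.shape else float(out[0])

    @property
    def bounds(self):
        return ((float(self.s_grid[0]), float(self.s_grid[-1])),
                (float(self.alpha_grid[0]), float(self.alpha_grid[-1])))


def fit_surface(surface: ResilienceSurface,
                smoothing: bool = False) -> SurfaceModel:
    """Interpolate grid-cell mean recovery times bilinearly.

    Requires a complete grid (no cell with every replicate censored).
    With ``smoothing`` the grid is first projected onto a surface
    non-increasing in both s and alpha.
    """
    Z = np.asarray(surface.mean, dtype=float)
    if np.isnan(Z).any():
        raise ValueError("incomplete grid: some cells have no uncensored "
                         "replicates")
    if smoothing:
        Z = monotone_smooth(Z)
    return SurfaceModel(np.asarray(surface.s_grid, dtype=float),
                        np.asarray(surface.alpha_grid, dtype=float),
                        Z, smoothing)


def iso_contour(model: SurfaceModel, level: float) -> list[np.ndarray]:
    """Marching-squares level set of the surface at the given recovery time.

    Returns ordered polylines as (k, 2) arrays of (s, alpha) points inside
    the grid domain; empty list if the level misses the surface range.
    """
    if not np.isfinite(level):
        raise ValueError("contour level must be finite")
    raw = _measure.find_contours(model.values, level)
    idx_s = np.arange(model.s_grid.size)
    idx_a = np.arange(model.alpha_grid.size)
    out = []
    for poly in raw:
        s = np.interp(poly[:, 0], idx_s, model.s_grid)
        a = np.interp(poly[:, 1], idx_a, model.alpha_grid)
        out.append(np.column_stack([s, a]))
    return out


@dataclass(frozen=True)
class BudgetModel:
    """Linear conservation budget over connection quality and quantity."""

    c_s: float        # cost per unit of connection quality
    c_alpha: float    # cost per connection
    budget: float     # total budget B

    def __post_init__(self):
        if self.c_s <= 0 or self.c_alpha <= 0:
            raise ValueError("unit costs must be positive")

    def cost(self, s, alpha):
        return self.c_s * np.asarray(s) + self.c_alpha * np.asarray(alpha)

    def affordable(self, s, alpha, atol: float = 1e-9):
        return self.cost(s, alpha) <= self.budget + atol


@dataclass(frozen=True)
class OffsetSolution:
    """Optimal (s, alpha) mix with its recovery time and budget."""

    s: float
    alpha: float
    recovery_time: float
    budget: float                    # cost of the solution
    offset: float = 0.0              # extra budget vs the reference (>= 0)
    binding: tuple[str, ...] = ()

    @property
    def alpha_int(self) -> int:
        """alpha rounded to a whole number of links for reporting."""
        return int(round(self.alpha))


def optimize_under_budget(model: SurfaceModel, budget: BudgetModel,
                          s_bounds: tuple[float, float] | None = None,
                          alpha_bounds: tuple[float, float] | None = None,
                          n_grid: int = 401) -> OffsetSolution:
    """Minimize interpolated recovery time subject to affordability.

    Dense-grid search over the feasible region followed by local
    refinement; ties broken toward lower cost, then lower s.  When the
    surface is strictly decreasing in both controls the optimum lies on
    the budget frontier (the tangency point of the budget line with the
    furthest reachable iso-resilience curve).
    """
    (s_lo, s_hi), (a_lo, a_hi) = model.bounds
    if s_bounds is not None:
        s_lo, s_hi = max(s_lo, s_bounds[0]), min(s_hi, s_bounds[1])
    if alpha_bounds is not None:
        a_lo, a_hi = max(a_lo, alpha_bounds[0]), min(a_hi, alpha_bounds[1])
    if s_lo > s_hi or a_lo > a_hi:
        raise ValueError("empty feasible region: incompatible bounds")
    if not budget.affordable(s_lo, a_lo):
        raise ValueError("empty feasible region: cheapest corner exceeds "
                         "the budget")
    ss = np.linspace(s_lo, s_hi, n_grid)
    aa = np.linspace(a_lo, a_hi, n_grid)
    S, A = np.meshgrid(ss, aa, indexing="ij")
    feas = budget.affordable(S, A)
    T = np.where(feas, model(S, A), np.inf)
    # lexicographic tie-break: recovery time, then cost, then s
    cost = budget.cost(S, A)
    order = np.lexsort((S.ravel(), cost.ravel(), np.round(T.ravel(), 12)))
    best = order[0]
    s0, a0 = S.ravel()[best], A.ravel()[best]

    def obj(z):
        return model(min(max(z[0], s_lo), s_hi), min(max(z[1], a_lo), a_hi))

    cons = [{"type": "ineq",
             "fun": lambda z: budget.budget - budget.cost(z[0], z[1])}]
    res = minimize(obj, [s0, a0], method="SLSQP", constraints=cons,
                   bounds=[(s_lo, s_hi), (a_lo, a_hi)],
                   options={"ftol": 1e-12, "maxiter": 200})
    s_star, a_star = (res.x if res.success and obj(res.x) <= model(s0, a0)
                      else (s0, a0))
    s_star = float(min(max(s_star, s_lo), s_hi))
    a_star = float(min(max(a_star, a_lo), a_hi))
    binding = []
    if abs(budget.cost(s_star, a_star) - budget.budget) <= 1e-6 * max(
            1.0, budget.budget):
        binding.append("budget")
    if abs(a_star - a_hi) < 1e-9:
        binding.append("alpha_upper")
    if abs(s_star - s_hi) < 1e-9:
        binding.append("s_upper")
    return OffsetSolution(s_star, a_star, float(model(s_star, a_star)),
                          float(budget.cost(s_star, a_star)),
                          binding=tuple(binding))


def min_budget_for_target(model: SurfaceModel, target: float,
                          alpha_cap: float, c_s: float, c_alpha: float,
                          reference_budget: float | None = None,
                          n_alpha: int = 401) -> OffsetSolution:
    """Cheapest (s, alpha) reaching the target recovery time under a cap.

    Minimizes ``c_s * s + c_alpha * alpha`` subject to
    ``T(s, alpha) <= target`` and ``alpha <= alpha_cap``.  Because T is
    non-increasing in s on a (smoothed) surface, the smallest feasible s
    at each alpha is found by bisection on ``T(s, alpha) - target``; the
    alpha with the lowest total cost wins.  ``offset`` reports the extra
    budget relative to ``reference_budget`` (e.g. the pre-disturbance
    spend), floored at zero.
    """
    if c_s <= 0 or c_alpha <= 0:
        raise ValueError("unit costs must be positive")
    (s_lo, s_hi), (a_lo, a_hi) = model.bounds
    a_hi = min(a_hi, float(alpha_cap))
    if a_hi < a_lo:
        raise ValueError("alpha cap below the surface domain")
    best = None
    for a in np.linspace(a_lo, a_hi, n_alpha):
        t_lo = model(s_hi, a)  # most quality -> fastest recovery
        if t_lo > target:
            continue
        if model(s_lo, a) <= target:
            s_min = s_lo
        else:
            s_min = brentq(lambda s: model(s, a) - target, s_lo, s_hi,
                           xtol=1e-10)
        cost = c_s * s_min + c_alpha * a
        if best is None or cost < best[0] - 1e-12:
            best = (cost, float(s_min), float(a))
    if best is None:
        raise ValueError(
            f"infeasible target {target}: even s={s_hi}, alpha={a_hi} "
            "does not recover fast enough")
    cost, s_star, a_star = best
    offset = (max(0.0, cost - reference_budget)
              if reference_budget is not None else 0.0)
    binding = ["target"]
    if abs(a_star - float(alpha_cap)) < 1e-9:
        binding.append("alpha_cap")
    return OffsetSolution(s_star, a_star, float(model(s_star, a_star)),
                          float(cost), offset, tuple(binding))
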