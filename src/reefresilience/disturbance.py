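"""Spatially random disturbance events.

A disturbance removes a fixed fraction of the biomass of every
sub-population within a given radius of a centre drawn uniformly on the
axis-aligned bounding box of the nodes.  By default centres are redrawn
until at least one node is hit, so every replicate represents an actual
perturbation; the redraw count is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NodeSet

#: default disturbance radius in model spatial units
DEFAULT_RADIUS = 0.4
#: default fraction of biomass removed inside the radius
DEFAULT_REMOVAL = 0.99


@dataclass(frozen=True)
class DisturbanceEvent:
    """One disturbance: centre, radius and proportional removal."""

    centre: tuple[float, float]
    radius: float = DEFAULT_RADIUS
    removal_fraction: float = DEFAULT_REMOVAL
    n_redraws: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.removal_fraction <= 1.0):
            raise ValueError("removal fraction must lie in [0, 1]")


def sample_event(nodes: NodeSet, radius: float = DEFAULT_RADIUS,
                 removal_fraction: float = DEFAULT_REMOVAL,
                 rng: int | np.random.Generator | None = None,
                 require_hit: bool = True,
                 max_redraws: int = 100_000) -> DisturbanceEvent:
    """Draw a disturbance centre uniformly on the nodes' bounding box.

    With ``require_hit`` (default) the centre is redrawn until at least one
    node lies within the radius, so the returned event always perturbs the
    system; misses are counted in ``n_redraws``.
    """
    gen = np.random.default_rng(rng)
    lo, hi = nodes.bounding_box()
    for redraw in range(max_redraws):
        centre = gen.uniform(lo, hi)
        if not require_hit:
            return DisturbanceEvent(tuple(centre), radius, removal_fraction,
                                    redraw)
        d = np.hypot(nodes.x - centre[0], nodes.y - centre[1])
        if np.any(d <= radius):
            return DisturbanceEvent(tuple(centre), radius, removal_fraction,
                                    redraw)
    raise RuntimeError(
        f"no disturbance centre hit a node in {max_redraws} draws; "
        "radius is too small for this geometry")


def disturbed_set(event: DisturbanceEvent, nodes: NodeSet) -> np.ndarray:
    """Boolean mask of nodes within the event radius (boundary inclusive)."""
    d = np.hypot(nodes.x - event.centre[0], nodes.y - event.centre[1])
    return d <= event.radius


def apply_event(state: np.ndarray, mask: np.ndarray,
                removal_fraction: float = DEFAULT_REMOVAL) -> np.ndarray:
    """Remove the given biomass fraction from masked nodes.

    Unmasked nodes are returned bit-identical; the input is not modified.
    """
    state = np.asarray(state, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != state.shape:
        raise ValueError("mask length must match state length")
    out = state.copy()
    out[mask] *= (1.0 - removal_fraction)
    return out
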