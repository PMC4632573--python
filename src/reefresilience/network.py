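"""Spatial reef network: nodes, distances and distance-decay dispersal links.

A metapopulation is a set of reef sub-populations at fixed Cartesian
coordinates.  A directed dispersal link from source ``j`` to destination
``i`` carries the base weight ``w = exp(-a*d - b)`` where ``d`` is the
Euclidean inter-reef distance; only weights strictly above a threshold are
retained, which bounds the network size.  The base weight is later scaled
by the connection quality ``s`` in the dynamics.  Link counts are reported
as ordered (directed) pairs throughout: the weights are symmetric, so every
retained unordered pair contributes two directed links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import integrate as _sciint
from scipy import optimize as _sciopt
from scipy.sparse import csgraph, csr_matrix
from scipy.spatial import distance_matrix as _distance_matrix

#: default exponential decay slope per model spatial unit
DECAY_SLOPE = 3.4
#: default decay intercept (sets the maximum base weight exp(-b))
DECAY_INTERCEPT = 3.91
#: strict lower threshold on retained base weights
WEIGHT_THRESHOLD = 0.01
#: reference directed link count of the calibrated 114-node reef network
REFERENCE_LINK_COUNT = 3904
#: reference node count of the calibrated reef network
REFERENCE_NODE_COUNT = 114


def cutoff_distance(a: float = DECAY_SLOPE, b: float = DECAY_INTERCEPT,
                    threshold: float = WEIGHT_THRESHOLD) -> float:
    """Distance beyond which the base weight drops to the threshold.

    Solves ``exp(-a*d - b) = threshold`` for ``d``; pairs farther apart
    than this are never linked.
    """
    return (np.log(1.0 / threshold) - b) / a


@dataclass(frozen=True)
class NodeSet:
    """Reef sub-population locations in the Cartesian plane.

    Coordinates are in model spatial units — the same units as the
    disturbance radius and the distances in the link rule.  Node ids are
    0-based positional indices into ``coords``.
    """

    coords: np.ndarray  # (n, 2) float64

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if coords.shape[0] < 2:
            raise ValueError("a NodeSet needs at least 2 nodes")
        if not np.all(np.isfinite(coords)):
            raise ValueError("node coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the axis-aligned bounding box."""
        return self.coords.min(axis=0), self.coords.max(axis=0)


def load_nodes(path: str | Path) -> NodeSet:
    """Read a node-coordinate file.

    The dialect is auto-detected: whitespace or comma delimited, optional
    header row, optional leading integer id column, ``#`` comments.  Rows
    are taken in file order and re-indexed 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"node file not found: {path}")
    rows = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if not rows and not header_seen:
                header_seen = True  # tolerate a single header row
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric field in {raw!r}")
        if len(vals) == 2:
            rows.append(vals)
        elif len(vals) >= 3:
            rows.append(vals[1:3])  # id x y
        else:
            raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
    if not rows:
        raise ValueError(f"no nodes in {path}")
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 nodes in {path}")
    return NodeSet(np.asarray(rows, dtype=float))


def write_nodes(nodes: NodeSet, path: str | Path) -> None:
    """Write a node file (1-based ids, as in typical ecological tables)."""
    with open(path, "w") as fh:
        fh.write("# node coordinates: id x y (ids 1-based)\n")
        for i, (x, y) in enumerate(nodes.coords, start=1):
            fh.write(f"{i} {x:.8g} {y:.8g}\n")


def pairwise_distances(nodes: NodeSet) -> np.ndarray:
    """Full symmetric Euclidean distance matrix between nodes."""
    return _distance_matrix(nodes.coords, nodes.coords)


@dataclass(frozen=True)
class LinkSet:
    """Directed dispersal links with distance-decay base weights.

    ``src[k] -> dst[k]`` carries base weight ``weight[k]``; weights are
    symmetric across direction and every stored weight exceeds the
    threshold strictly.  ``n_nodes`` fixes the index range.
    """

    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray
    n_nodes: int
    a: float = DECAY_SLOPE
    b: float = DECAY_INTERCEPT
    threshold: float = WEIGHT_THRESHOLD

    def __len__(self) -> int:
        return self.src.shape[0]

    @property
    def n_links(self) -> int:
        """Number of ordered (directed) links."""
        return len(self)

    def out_degree(self) -> np.ndarray:
        return np.bincount(self.src, minlength=self.n_nodes)

    def weight_matrix(self) -> np.ndarray:
        """Dense ``(n, n)`` matrix ``W[j, i]`` = base weight of link j→i."""
        W = np.zeros((self.n_nodes, self.n_nodes))
        W[self.src, self.dst] = self.weight
        return W

    def subset(self, mask: np.ndarray) -> "LinkSet":
        mask = np.asarray(mask, dtype=bool)
        return LinkSet(self.src[mask], self.dst[mask], self.weight[mask],
                       self.n_nodes, self.a, self.b, self.threshold)


@dataclass(frozen=True)
class LinkSubset:
    """A boolean inclusion mask over a parent :class:`LinkSet`."""

    parent: LinkSet
    mask: np.ndarray  # bool over parent links
    alpha: int

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape[0] != len(self.parent):
            raise ValueError("mask length must match parent link count")
        if int(mask.sum()) != self.alpha:
            raise ValueError("mask does not retain exactly alpha links")
        object.__setattr__(self, "mask", mask)

    def to_linkset(self) -> LinkSet:
        return self.parent.subset(self.mask)


def build_links(dist: np.ndarray, a: float = DECAY_SLOPE,
                b: float = DECAY_INTERCEPT,
                threshold: float = WEIGHT_THRESHOLD) -> LinkSet:
    """Threshold the distance-decay kernel into a directed link set.

    Keeps every ordered pair ``(j, i)``, ``j != i``, whose base weight
    ``exp(-a*d - b)`` strictly exceeds ``threshold``.  Self-links are
    excluded: migration from a reef to itself is meaningless even though
    the kernel value at zero distance exceeds the threshold.
    """
    if a <= 0:
        raise ValueError("decay slope a must be positive")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    W = np.exp(-a * dist - b)
    keep = W > threshold
    np.fill_diagonal(keep, False)
    src, dst = np.nonzero(keep)
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    return LinkSet(src.astype(np.int64), dst.astype(np.int64),
                   W[src, dst], n, a, b, threshold)


def complete_links(n: int, weight: float = 1.0) -> LinkSet:
    """All ordered pairs with a constant base weight (no self-links).

    Used by the no-spatial-effect sensitivity scenario, in which every
    pair of reefs is equally connected regardless of distance.
    """
    src, dst = np.nonzero(~np.eye(n, dtype=bool))
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    return LinkSet(src.astype(np.int64), dst.astype(np.int64),
                   np.full(src.shape[0], float(weight)), n, threshold=0.0)


def write_links(links: LinkSet, path: str | Path) -> None:
    """Write links as ``source,target,weight`` CSV (1-based ids, 6 s.f.)."""
    with open(path, "w") as fh:
        fh.write("# directed links: source,target,weight (ids 1-based)\n")
        fh.write("source,target,weight\n")
        for j, i, w in zip(links.src, links.dst, links.weight):
            fh.write(f"{j + 1},{i + 1},{w:.6g}\n")


def load_links(path: str | Path, n_nodes: int | None = None) -> LinkSet:
    """Read a link file with columns ``source target [weight]``.

    Accepts comma or whitespace delimiters, ``#`` comments and an optional
    header.  Ids in files are 1-based and converted to 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"link file not found: {path}")
    srcs, dsts, ws = [], [], []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if not srcs and not header_seen:
                header_seen = True
                continue
            raise ValueError(f"{path}:{lineno}: malformed row {raw!r}")
        if len(vals) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
        s, t = int(vals[0]) - 1, int(vals[1]) - 1
        if s < 0 or t < 0:
            raise ValueError(f"{path}:{lineno}: ids must be 1-based positive")
        srcs.append(s)
        dsts.append(t)
        ws.append(vals[2] if len(vals) >= 3 else np.nan)
    if not srcs:
        raise ValueError(f"no links in {path}")
    src = np.asarray(srcs, dtype=np.int64)
    dst = np.asarray(dsts, dtype=np.int64)
    n = n_nodes if n_nodes is not None else int(max(src.max(), dst.max())) + 1
    if src.max() >= n or dst.max() >= n:
        raise ValueError("link ids outside node range")
    order = np.lexsort((dst, src))
    return LinkSet(src[order], dst[order], np.asarray(ws)[order], n)


@dataclass(frozen=True)
class LinkDiff:
    """Report of the differences between two directed link sets."""

    only_in_first: list[tuple[int, int]]
    only_in_second: list[tuple[int, int]]
    max_weight_discrepancy: float
    n_common: int

    @property
    def is_empty(self) -> bool:
        return (not self.only_in_first and not self.only_in_second
                and (np.isnan(self.max_weight_discrepancy)
                     or self.max_weight_discrepancy < 1e-6))


def compare_links(built: LinkSet, loaded: LinkSet) -> LinkDiff:
    """Diff two link sets by ordered pair and by weight.

    Weight discrepancies are computed over common pairs only; NaN weights
    (link files without a weight column) are ignored.
    """
    a = {(int(s), int(d)): float(w)
         for s, d, w in zip(built.src, built.dst, built.weight)}
    b = {(int(s), int(d)): float(w)
         for s, d, w in zip(loaded.src, loaded.dst, loaded.weight)}
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    common = set(a) & set(b)
    diffs = [abs(a[k] - b[k]) for k in common
             if not (np.isnan(a[k]) or np.isnan(b[k]))]
    maxd = max(diffs) if diffs else float("nan")
    return LinkDiff(only_a, only_b, maxd, len(common))


def sample_links(links: LinkSet, alpha: int,
                 rng: int | np.random.Generator | None = None) -> LinkSubset:
    """Uniform random subset of ``alpha`` directed links without replacement."""
    if not (1 <= alpha <= len(links)):
        raise ValueError(f"alpha={alpha} outside [1, {len(links)}]")
    gen = np.random.default_rng(rng)
    idx = gen.choice(len(links), size=alpha, replace=False)
    mask = np.zeros(len(links), dtype=bool)
    mask[idx] = True
    return LinkSubset(links, mask, int(alpha))


# ---------------------------------------------------------------------------
# Synthetic reef strip
# ---------------------------------------------------------------------------

#: default strip width (cross-shore extent) in model units; about half the
#: default link cutoff distance, so the strip is effectively elongated
DEFAULT_STRIP_WIDTH = 0.1
#: default target mean out-degree, matching the calibrated reef network
DEFAULT_TARGET_DEGREE = REFERENCE_LINK_COUNT / REFERENCE_NODE_COUNT


def _p_within(length: float, width: float, c: float) -> float:
    """P(two uniform points in a width x length rectangle are closer than c)."""
    def inner(v):
        um = min(np.sqrt(max(c * c - v * v, 0.0)), width)
        return (2 * um / width - um * um / width ** 2) * 2 * (length - v) / length ** 2
    val, _ = _sciint.quad(inner, 0.0, min(c, length), limit=200)
    return val


def solve_strip_length(n: int, target_degree: float,
                       width: float = DEFAULT_STRIP_WIDTH,
                       a: float = DECAY_SLOPE, b: float = DECAY_INTERCEPT,
                       threshold: float = WEIGHT_THRESHOLD) -> float:
    """Strip length whose expected directed link count hits the target degree.

    For uniform placement the expected number of directed links is
    ``n*(n-1)*P(d < cutoff)``; this inverts that relation for the length.
    """
    c = cutoff_distance(a, b, threshold)
    target_p = target_degree / (n - 1)
    if target_p >= 1.0:
        raise ValueError("target degree unattainable: would need P >= 1")
    f = lambda L: _p_within(L, width, c) - target_p
    return float(_sciopt.brentq(f, max(c, width) * 1.0001, 200.0))


def _rescale_to_degree(coords: np.ndarray, target_links: int,
                       a: float = DECAY_SLOPE, b: float = DECAY_INTERCEPT,
                       threshold: float = WEIGHT_THRESHOLD) -> np.ndarray:
    """Uniformly rescale coordinates so the link rule keeps target_links.

    A pair is linked iff its distance is strictly below the cutoff, so the
    scale factor is chosen to put exactly ``target_links / 2`` unordered
    pairs below it (midpoint between the bracketing order statistics).
    """
    n = coords.shape[0]
    d = _distance_matrix(coords, coords)
    pairs = np.sort(d[np.triu_indices(n, k=1)])
    k = int(round(target_links / 2))
    if not (1 <= k <= pairs.size):
        raise ValueError(f"target link count {target_links} out of range "
                         f"for n={n}")
    c = cutoff_distance(a, b, threshold)
    upper = pairs[k - 1]
    lower = pairs[k] if k < pairs.size else pairs[k - 1] * 1.01
    if lower <= upper:  # tied distances: exact count unattainable
        warnings.warn("tied pair distances; link count may be off by ties")
        lower = np.nextafter(upper, np.inf)
    return coords * (c / (0.5 * (upper + lower)))


def synthesize_network(n: int = REFERENCE_NODE_COUNT,
                       extent: tuple[float, float] | None = None,
                       rng: int | np.random.Generator | None = None,
                       layout: str = "clustered",
                       n_clusters: int = 12,
                       cluster_spread: float = 0.05,
                       target_mean_out_degree: float = DEFAULT_TARGET_DEGREE,
                       rescale: bool = True,
                       max_attempts: int = 20) -> NodeSet:
    """Place ``n`` reef nodes in an elongated alongshore strip.

    The strip's long axis is ``y`` (a latitude proxy for the growth-rate
    gradient scenarios).  The default ``clustered`` layout strings cluster
    centres along the strip and scatters nodes around them, mimicking the
    patchy reef habitat of a fringing reef; ``uniform`` scatters nodes
    evenly.  With ``rescale`` (default) the layout is uniformly rescaled so
    the default link rule retains ``round(n * target_mean_out_degree)``
    directed links exactly (up to distance ties) — for the default
    114-node network, 3904 links.  The draw is repeated (seeded,
    deterministic) until the resulting network is connected.
    """
    if n < 2:
        raise ValueError("need n >= 2 nodes")
    # small networks cannot carry the reference degree; cap it
    target_mean_out_degree = min(target_mean_out_degree, 0.9 * (n - 1))
    if extent is None:
        if layout == "uniform":
            extent = (DEFAULT_STRIP_WIDTH,
                      solve_strip_length(n, target_mean_out_degree))
        else:
            extent = (DEFAULT_STRIP_WIDTH, 1.3)
    width, length = extent
    if width <= 0 or length <= 0:
        raise ValueError("extent must be positive")
    target_links = min(int(round(n * target_mean_out_degree)), n * (n - 1))
    gen = np.random.default_rng(rng)
    nodes = None
    for _ in range(max_attempts):
        if layout == "uniform":
            coords = np.column_stack([gen.uniform(0, width, n),
                                      gen.uniform(0, length, n)])
        elif layout == "clustered":
            centres = np.column_stack([
                np.full(n_clusters, width / 2.0),
                np.sort(gen.uniform(0, length, n_clusters))])
            idx = gen.integers(0, n_clusters, n)
            coords = centres[idx] + gen.normal(0, cluster_spread, (n, 2))
        else:
            raise ValueError(f"unknown layout {layout!r}")
        if rescale:
            coords = _rescale_to_degree(coords, target_links)
        candidate = NodeSet(coords)
        links = build_links(pairwise_distances(candidate))
        adj = csr_matrix((np.ones(len(links)), (links.src, links.dst)),
                         shape=(n, n))
        n_comp, _ = csgraph.connected_components(adj, directed=False)
        if n_comp == 1:
            nodes = candidate
            break
    if nodes is None:
        warnings.warn("could not draw a connected network; using last draw")
        nodes = candidate
    mean_deg = len(build_links(pairwise_distances(nodes))) / n
    if abs(mean_deg - target_mean_out_degree) > 0.5 * target_mean_out_degree:
        warnings.warn(
            f"realised mean out-degree {mean_deg:.1f} far from target "
            f"{target_mean_out_degree:.1f}; extent may be incompatible")
    return nodes


@dataclass(frozen=True)
class ReefNetwork:
    """Nodes, distances and full thresholded link set of one reef system."""

    nodes: NodeSet
    distances: np.ndarray = field(repr=False)
    links: LinkSet = field(repr=False)

    @property
    def n(self) -> int:
        return self.nodes.n

    @classmethod
    def from_nodes(cls, nodes: NodeSet, a: float = DECAY_SLOPE,
                   b: float = DECAY_INTERCEPT,
                   threshold: float = WEIGHT_THRESHOLD) -> "ReefNetwork":
        d = pairwise_distances(nodes)
        return cls(nodes, d, build_links(d, a, b, threshold))

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "ReefNetwork":
        return cls.from_nodes(load_nodes(path), **kwargs)

    @classmethod
    def synthetic(cls, n: int = REFERENCE_NODE_COUNT,
                  rng: int | np.random.Generator | None = None,
                  **kwargs) -> "ReefNetwork":
        return cls.from_nodes(synthesize_network(n, rng=rng, **kwargs))

    def with_links(self, links: LinkSet) -> "ReefNetwork":
        return ReefNetwork(self.nodes, self.distances, links)

    def report(self) -> dict:
        deg = self.links.out_degree()
        return {
            "n_nodes": self.n,
            "n_links": len(self.links),
            "mean_out_degree": float(deg.mean()),
            "min_out_degree": int(deg.min()),
            "max_out_degree": int(deg.max()),
            "cutoff_distance": cutoff_distance(
                self.links.a, self.links.b, self.links.threshold),
        }
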