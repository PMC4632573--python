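"""Node files, distances, the distance-decay link rule and subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reefresilience as rr
from reefresilience.network import (DECAY_INTERCEPT, DECAY_SLOPE,
                                    WEIGHT_THRESHOLD, _rescale_to_degree)


# ---------------------------------------------------------------------------
# node files and distances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("content,n", [
    ("0 0\n1 0\n0 1\n", 3),                                # whitespace x y
    ("x,y\n0,0\n1,0\n0,1\n", 3),                           # csv with header
    ("# comment\n1 0.0 0.0\n2 1.0 0.0\n3 0.0 1.0\n", 3),   # id x y
    ("id,x,y\n1,0,0\n2,3,4\n", 2),
])
def test_load_nodes_dialects(tmp_path, content, n):
    path = tmp_path / "nodes.txt"
    path.write_text(content)
    nodes = rr.load_nodes(path)
    assert nodes.n == n


@pytest.mark.parametrize("content,err", [
    ("", "no nodes"),
    ("0 0\n", "fewer than 2"),
    ("0 0\n1 abc\n", "non-numeric"),
])
def test_load_nodes_errors(tmp_path, content, err):
    path = tmp_path / "nodes.txt"
    path.write_text(content)
    with pytest.raises(ValueError, match=err):
        rr.load_nodes(path)


def test_load_nodes_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        rr.load_nodes(tmp_path / "absent.txt")


def test_node_roundtrip(tmp_path, small_net):
    path = tmp_path / "nodes.txt"
    rr.write_nodes(small_net.nodes, path)
    again = rr.load_nodes(path)
    assert np.allclose(again.coords, small_net.nodes.coords)


def test_pairwise_distances_345():
    nodes = rr.NodeSet(np.array([[0.0, 0.0], [3.0, 4.0]]))
    d = rr.pairwise_distances(nodes)
    assert d[0, 1] == pytest.approx(5.0)
    assert d[0, 0] == 0.0 and d[1, 1] == 0.0


def test_pairwise_distances_brute_force_oracle():
    rng = np.random.default_rng(42)
    coords = rng.uniform(-5, 5, (10, 2))
    d = rr.pairwise_distances(rr.NodeSet(coords))
    for i in range(10):
        for j in range(10):
            expect = np.hypot(*(coords[i] - coords[j]))
            assert d[i, j] == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# link rule
# ---------------------------------------------------------------------------

def test_link_weight_formula_and_threshold():
    # 0.1 apart: w = exp(-4.25) ~ 0.01426 > 0.01, kept both ways
    d = np.array([[0.0, 0.1], [0.1, 0.0]])
    links = rr.build_links(d)
    assert len(links) == 2
    assert links.weight[0] == pytest.approx(np.exp(-3.4 * 0.1 - 3.91))
    assert links.weight[0] == pytest.approx(0.014264, abs=1e-6)
    # 0.25 apart: w ~ 0.00857 < 0.01, excluded
    d = np.array([[0.0, 0.25], [0.25, 0.0]])
    assert len(rr.build_links(d)) == 0


def test_cutoff_distance_value():
    c = rr.cutoff_distance()
    assert c == pytest.approx(0.20446, abs=1e-5)
    # strictness at the boundary: w(c) == threshold exactly -> excluded
    d = np.array([[0.0, c], [c, 0.0]])
    assert len(rr.build_links(d)) == 0
    eps = 1e-9
    d = np.array([[0.0, c - eps], [c - eps, 0.0]])
    assert len(rr.build_links(d)) == 2


def test_no_self_links_even_at_zero_distance():
    # duplicate coordinates: distinct nodes at d=0 get the max base weight,
    # but a node never links to itself
    d = np.zeros((3, 3))
    links = rr.build_links(d)
    assert len(links) == 6
    assert np.all(links.src != links.dst)
    assert np.allclose(links.weight, np.exp(-DECAY_INTERCEPT))


def test_threshold_soundness_exhaustive(small_net):
    """Stored iff strictly above threshold, by full recomputation."""
    links = small_net.links
    d = small_net.distances
    W = np.exp(-DECAY_SLOPE * d - DECAY_INTERCEPT)
    stored = set(zip(links.src.tolist(), links.dst.tolist()))
    n = small_net.n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            assert ((i, j) in stored) == (W[i, j] > WEIGHT_THRESHOLD)
    # weight symmetry
    lut = {(s, t): w for s, t, w in
           zip(links.src.tolist(), links.dst.tolist(), links.weight)}
    for (s, t), w in lut.items():
        assert lut[(t, s)] == pytest.approx(w, abs=1e-15)


def test_distance_monotonicity(small_net):
    links = small_net.links
    d = small_net.distances[links.src, links.dst]
    order = np.argsort(d)
    w = links.weight[order]
    assert np.all(np.diff(w) <= 1e-15)


def test_build_links_validation():
    d = np.zeros((2, 2))
    with pytest.raises(ValueError, match="slope"):
        rr.build_links(d, a=-1.0)
    with pytest.raises(ValueError, match="threshold"):
        rr.build_links(d, threshold=1.5)


# ---------------------------------------------------------------------------
# link files and comparison
# ---------------------------------------------------------------------------

def test_link_roundtrip_empty_diff(tmp_path, small_net):
    path = tmp_path / "links.csv"
    rr.write_links(small_net.links, path)
    loaded = rr.load_links(path, n_nodes=small_net.n)
    diff = rr.compare_links(small_net.links, loaded)
    assert diff.is_empty
    assert diff.n_common == len(small_net.links)


def test_compare_links_injected_discrepancies(tmp_path, small_net):
    links = small_net.links
    # drop one directed link
    mask = np.ones(len(links), dtype=bool)
    mask[5] = False
    dropped = links.subset(mask)
    diff = rr.compare_links(links, dropped)
    assert diff.only_in_first == [(int(links.src[5]), int(links.dst[5]))]
    assert not diff.only_in_second
    # perturb one weight
    w = links.weight.copy()
    w[7] += 0.005
    perturbed = rr.LinkSet(links.src, links.dst, w, links.n_nodes)
    diff = rr.compare_links(links, perturbed)
    assert diff.max_weight_discrepancy == pytest.approx(0.005)
    assert not diff.is_empty


def test_load_links_errors(tmp_path):
    bad = tmp_path / "links.csv"
    bad.write_text("source,target,weight\n1,2,0.5\nx,y,z\n")
    with pytest.raises(ValueError, match="malformed"):
        rr.load_links(bad)
    out_of_range = tmp_path / "links2.csv"
    out_of_range.write_text("1,2,0.5\n9,1,0.5\n")
    with pytest.raises(ValueError, match="outside node range"):
        rr.load_links(out_of_range, n_nodes=3)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def test_sample_links_identity_and_membership(small_net):
    links = small_net.links
    full = rr.sample_links(links, len(links), rng=0)
    assert full.alpha == len(links)
    assert full.mask.all()
    sub = rr.sample_links(links, 20, rng=1)
    assert int(sub.mask.sum()) == 20
    assert len(sub.to_linkset()) == 20


def test_sample_links_seeded_and_complement(small_net):
    links = small_net.links
    a = rr.sample_links(links, 30, rng=7)
    b = rr.sample_links(links, 30, rng=7)
    assert np.array_equal(a.mask, b.mask)
    # union of a subset and its complement reconstructs the parent
    complement = links.subset(~a.mask)
    rebuilt = sorted(set(zip(a.to_linkset().src, a.to_linkset().dst))
                     | set(zip(complement.src, complement.dst)))
    assert rebuilt == sorted(zip(links.src.tolist(), links.dst.tolist()))


def test_sample_links_range_errors(small_net):
    with pytest.raises(ValueError):
        rr.sample_links(small_net.links, 0)
    with pytest.raises(ValueError):
        rr.sample_links(small_net.links, len(small_net.links) + 1)


def test_sample_links_uniform_inclusion(small_net):
    """Half-size subsets include each link with frequency 1/2."""
    links = small_net.links
    m = len(links)
    alpha = m // 2
    n_draws = 20_000
    rng = np.random.default_rng(123)
    counts = np.zeros(m)
    for _ in range(n_draws):
        counts += rr.sample_links(links, alpha, rng).mask
    p = alpha / m
    se = np.sqrt(p * (1 - p) / n_draws)
    freq = counts / n_draws
    assert np.all(np.abs(freq - p) < 3.5 * se + 1e-12)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def test_synthesize_deterministic():
    a = rr.synthesize_network(114, rng=5)
    b = rr.synthesize_network(114, rng=5)
    assert np.array_equal(a.coords, b.coords)


def test_synthesize_two_close_nodes_linked():
    nodes = rr.synthesize_network(2, extent=(0.1, 0.1), rng=0, rescale=False)
    links = rr.build_links(rr.pairwise_distances(nodes))
    assert len(links) == 2


def test_synthesize_reference_density(reef114):
    """Default 114-node strip realizes the calibrated link budget."""
    n_links = len(reef114.links)
    assert abs(n_links - 3904) <= 0.25 * 3904
    deg = reef114.links.out_degree()
    assert 20 < deg.mean() < 50
    # elongated strip: alongshore span much larger than cross-shore
    span = reef114.nodes.coords.max(0) - reef114.nodes.coords.min(0)
    assert span[1] > 3 * span[0]


def test_synthesize_uniform_layout_density():
    net = rr.ReefNetwork.from_nodes(
        rr.synthesize_network(114, rng=2, layout="uniform"))
    assert abs(len(net.links) - 3904) <= 0.25 * 3904


def test_synthesize_validation():
    with pytest.raises(ValueError, match="n >= 2"):
        rr.synthesize_network(1)
    with pytest.raises(ValueError, match="layout"):
        rr.synthesize_network(10, layout="ring")


def test_rescale_targets_exact_count():
    rng = np.random.default_rng(9)
    coords = rng.uniform(0, 1, (40, 2))
    scaled = _rescale_to_degree(coords, 300)
    links = rr.build_links(rr.pairwise_distances(rr.NodeSet(scaled)))
    assert len(links) == 300


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_subset_mask_cardinality_property(seed):
    """|subset| == alpha exactly for random alpha and seed."""
    d = np.abs(np.subtract.outer(np.linspace(0, 0.5, 12),
                                 np.linspace(0, 0.5, 12)))
    links = rr.build_links(d)
    rng = np.random.default_rng(seed)
    alpha = int(rng.integers(1, len(links) + 1))
    sub = rr.sample_links(links, alpha, rng)
    assert int(sub.mask.sum()) == alpha
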