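"""Shared fixtures: tiny hand-built trees and a random-tree factory."""

from __future__ import annotations

import numpy as np
import pytest

from pulmotree.vessel_graph import Node, Segment, VesselTree, build_tree


def make_path_tree(lengths=(10.0,), radii=None, sample_id="path") -> VesselTree:
    """A chain root -> n1 -> ... with given segment lengths (and radii)."""
    radii = radii if radii is not None else [5.0] * len(lengths)
    nodes = [Node(0, 0, 0, 0, kind="root")]
    segments = []
    for i, (L, r) in enumerate(zip(lengths, radii), start=1):
        nodes.append(Node(i, 0, 0, float(i), kind="junction"))
        segments.append(Segment(i, i - 1, i, float(L), r))
    return build_tree(sample_id, "", nodes, segments, root=0)


def make_perfect_binary(depth: int, with_root_edge: bool = True) -> VesselTree:
    """Perfect binary tree of the given depth below a single trunk edge."""
    nodes = [Node(0, kind="root")]
    segments = []
    next_id = [1]

    def grow(parent: int, level: int, radius: float) -> None:
        nid = next_id[0]
        next_id[0] += 1
        nodes.append(Node(nid, kind="junction"))
        segments.append(Segment(nid, parent, nid, 10.0, radius))
        if level < depth:
            grow(nid, level + 1, radius * 0.8)
            grow(nid, level + 1, radius * 0.8)

    if with_root_edge:
        trunk = next_id[0]
        next_id[0] += 1
        nodes.append(Node(trunk, kind="junction"))
        segments.append(Segment(trunk, 0, trunk, 10.0, 50.0))
        grow(trunk, 1, 40.0)
        grow(trunk, 1, 40.0)
    else:
        grow(0, 1, 40.0)
        grow(0, 1, 40.0)
    return build_tree("binary", "", nodes, segments, root=0)


def make_comb(n_trunk: int = 4, trunk_radius: float = 20.0, lateral_radius: float = 6.0) -> VesselTree:
    """Monopodial comb: a trunk of ``n_trunk`` segments with one single-leaf
    lateral at each interior trunk node."""
    nodes = [Node(0, kind="root")]
    segments = []
    nid = 1
    prev = 0
    trunk_nodes = []
    for i in range(n_trunk):
        nodes.append(Node(nid, kind="junction"))
        segments.append(Segment(len(segments) + 1, prev, nid, 10.0, trunk_radius))
        trunk_nodes.append(nid)
        prev = nid
        nid += 1
    for t in trunk_nodes[:-1]:
        nodes.append(Node(nid, kind="endpoint"))
        segments.append(Segment(len(segments) + 1, t, nid, 5.0, lateral_radius))
        nid += 1
    return build_tree("comb", "", nodes, segments, root=0)


def random_tree(
    rng: np.random.Generator, max_segments: int = 50, tapering: bool = False
) -> VesselTree:
    """A uniformly random recursive tree with random geometry.

    Node i > 0 attaches to a uniformly chosen earlier node, which covers
    chains, stars, and everything between — deliberately broader than the
    anatomical generator.  With ``tapering=True`` every child radius is a
    fraction (0.3–0.95) of its parent's, as in physical vessels.
    """
    n = int(rng.integers(1, max_segments + 1))
    nodes = [Node(0, kind="root")]
    segments = []
    radius_below: dict[int, float] = {0: float(rng.uniform(30.0, 60.0))}
    for i in range(1, n + 1):
        parent = int(rng.integers(0, i))
        if tapering:
            radius = radius_below[parent] * float(rng.uniform(0.3, 0.95))
        else:
            radius = float(rng.uniform(1.0, 60.0))
        radius_below[i] = radius
        nodes.append(Node(i, kind="junction"))
        segments.append(
            Segment(
                segment_id=i,
                proximal_node=parent,
                distal_node=i,
                length=float(rng.uniform(1.0, 100.0)),
                mean_radius=radius,
            )
        )
    return build_tree("random", "", nodes, segments, root=0)


@pytest.fixture
def path_tree() -> VesselTree:
    return make_path_tree()


@pytest.fixture
def comb_tree() -> VesselTree:
    return make_comb()


@pytest.fixture
def binary_tree() -> VesselTree:
    return make_perfect_binary(2)


@pytest.fixture
def rng() -> np.random.Generator:
    # fresh, fixed-seed stream per test so results never depend on test order
    return np.random.default_rng(20230626)
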