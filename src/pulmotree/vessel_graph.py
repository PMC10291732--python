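"""Rooted-tree data model for segmented vascular trees.

A skeletonized vessel tree is represented as a rooted tree of :class:`Node`
objects connected by :class:`Segment` objects.  A segment is the stretch of
vessel between two consecutive branch points (or between a branch point and
an end point); each segment carries its centerline length and mean lumen
radius in micrometres and a unique integer identifier that downstream
modules use to attach morphometric measurements and group labels.

The module provides

* validated construction (:func:`build_tree`) that orients segments away
  from a declared root,
* GraphML and CSV edge-list I/O (:func:`read_tree` / :func:`write_tree`),
* contraction of degree-2 chains into single segments
  (:func:`contract_degree2`), and
* merging of disjoint trees under a new artificial root
  (:func:`merge_trees`), mirroring the repair needed when the arterial root
  of a sample is damaged and the tree splits in two.

All lengths and radii are micrometres.  Artificial nodes/segments are
bookkeeping devices: they carry no measurements (length 0, missing radius)
and are excluded from every morphometric feature table downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Node",
    "Segment",
    "VesselTree",
    "TreeStructureError",
    "build_tree",
    "read_tree",
    "write_tree",
    "contract_degree2",
    "merge_trees",
]

NODE_KINDS = ("root", "junction", "endpoint", "artificial")


class TreeStructureError(ValueError):
    """Raised when a vessel tree violates a structural invariant."""


@dataclass(frozen=True)
class Node:
    """A branch point, end point or artificial connector of the tree."""

    node_id: int
    x: float | None = None
    y: float | None = None
    z: float | None = None
    kind: str = "junction"

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        for c in (self.x, self.y, self.z):
            if c is not None and not math.isfinite(c):
                raise ValueError(f"non-finite coordinate on node {self.node_id}")


@dataclass(frozen=True)
class Segment:
    """A vessel stretch between two consecutive branch/end points.

    ``proximal_node`` is the end closer to the root (fewer edges on the
    node path); orientation is derived from the declared root, never from
    file order.
    """

    segment_id: int
    proximal_node: int
    distal_node: int
    length: float
    mean_radius: float | None = None
    is_artificial: bool = False

    def __post_init__(self) -> None:
        if self.is_artificial:
            if self.length < 0:
                raise ValueError(f"negative length on segment {self.segment_id}")
        elif not (self.length > 0) or not math.isfinite(self.length):
            raise ValueError(
                f"segment {self.segment_id}: length must be > 0 (got {self.length})"
            )
        if self.mean_radius is not None and (
            self.mean_radius < 0 or not math.isfinite(self.mean_radius)
        ):
            raise ValueError(f"segment {self.segment_id}: invalid mean_radius")


@dataclass
class VesselTree:
    """A validated, rooted vascular tree for one sample."""

    sample_id: str
    group_label: str
    nodes: dict[int, Node]
    segments: dict[int, Segment]
    root: int

    # -- structure queries -------------------------------------------------
    def children_of_node(self, node_id: int) -> list[Segment]:
        """Segments whose proximal end is ``node_id``, ordered by segment_id."""
        return sorted(
            (s for s in self.segments.values() if s.proximal_node == node_id),
            key=lambda s: s.segment_id,
        )

    def parent_segment_of_node(self, node_id: int) -> Segment | None:
        for s in self.segments.values():
            if s.distal_node == node_id:
                return s
        return None

    def child_segments(self, segment_id: int) -> list[Segment]:
        return self.children_of_node(self.segments[segment_id].distal_node)

    def parent_segment(self, segment_id: int) -> Segment | None:
        return self.parent_segment_of_node(self.segments[segment_id].proximal_node)

    def root_segments(self) -> list[Segment]:
        return self.children_of_node(self.root)

    def leaf_segments(self) -> list[Segment]:
        proximals = {s.proximal_node for s in self.segments.values()}
        return sorted(
            (s for s in self.segments.values() if s.distal_node not in proximals),
            key=lambda s: s.segment_id,
        )

    def total_length(self, include_artificial: bool = True) -> float:
        return sum(
            s.length
            for s in self.segments.values()
            if include_artificial or not s.is_artificial
        )

    def validate(self) -> None:
        """Check every structural invariant; raise TreeStructureError on failure."""
        _validate(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VesselTree):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.group_label == other.group_label
            and self.root == other.root
            and self.nodes == other.nodes
            and self.segments == other.segments
        )


# ---------------------------------------------------------------------------
# construction & validation


def build_tree(
    sample_id: str,
    group_label: str,
    nodes: Iterable[Node],
    segments: Iterable[Segment],
    root: int,
) -> VesselTree:
    """Assemble and validate a tree, orienting segments away from ``root``.

    Segment endpoint order in the input is ignored; the proximal end of each
    segment is recomputed as the endpoint nearer the root.
    """
    node_map: dict[int, Node] = {}
    for n in nodes:
        if n.node_id in node_map:
            raise TreeStructureError(f"duplicate node_id {n.node_id}")
        node_map[n.node_id] = n
    seg_map: dict[int, Segment] = {}
    for s in segments:
        if s.segment_id in seg_map:
            raise TreeStructureError(f"duplicate segment_id {s.segment_id}")
        seg_map[s.segment_id] = s
    if root not in node_map:
        raise TreeStructureError(f"declared root {root} not among nodes")

    oriented = _orient_from_root(node_map, seg_map, root)
    tree = VesselTree(sample_id, group_label, node_map, oriented, root)
    _validate(tree)
    return tree


def _orient_from_root(
    nodes: dict[int, Node], segments: dict[int, Segment], root: int
) -> dict[int, Segment]:
    """BFS from the root over the undirected edge set; flip segments as needed."""
    adjacency: dict[int, list[Segment]] = {nid: [] for nid in nodes}
    for s in segments.values():
        for end in (s.proximal_node, s.distal_node):
            if end not in nodes:
                raise TreeStructureError(
                    f"segment {s.segment_id} references unknown node {end}"
                )
        if s.proximal_node == s.distal_node:
            raise TreeStructureError(
                f"cycle detected: segment {s.segment_id} is a self-loop on node "
                f"{s.proximal_node}"
            )
        adjacency[s.proximal_node].append(s)
        adjacency[s.distal_node].append(s)

    oriented: dict[int, Segment] = {}
    depth = {root: 0}
    frontier = [root]
    while frontier:
        nxt: list[int] = []
        for u in frontier:
            for s in adjacency[u]:
                if s.segment_id in oriented:
                    continue
                v = s.distal_node if s.proximal_node == u else s.proximal_node
                if v in depth:
                    raise TreeStructureError(
                        f"cycle detected at segment {s.segment_id} "
                        f"({s.proximal_node}-{s.distal_node})"
                    )
                depth[v] = depth[u] + 1
                oriented[s.segment_id] = (
                    s if s.proximal_node == u else replace(s, proximal_node=u, distal_node=v)
                )
                nxt.append(v)
        frontier = nxt

    unreached = set(nodes) - set(depth)
    if unreached:
        # each unreachable component contributes one candidate root
        candidates = _component_candidates(nodes, segments, unreached)
        raise TreeStructureError(
            "multiple roots: tree is disconnected; candidate roots "
            f"{sorted(candidates)} in addition to declared root {root}"
        )
    return oriented


def _component_candidates(
    nodes: dict[int, Node], segments: dict[int, Segment], unreached: set[int]
) -> list[int]:
    g = nx.Graph()
    g.add_nodes_from(unreached)
    for s in segments.values():
        if s.proximal_node in unreached and s.distal_node in unreached:
            g.add_edge(s.proximal_node, s.distal_node)
    return [min(c) for c in nx.connected_components(g)]


def _validate(tree: VesselTree) -> None:
    n_nodes, n_segs = len(tree.nodes), len(tree.segments)
    if tree.root not in tree.nodes:
        raise TreeStructureError(f"root {tree.root} not among nodes")
    if n_segs != n_nodes - 1:
        raise TreeStructureError(
            f"tree must satisfy #segments = #nodes - 1 (got {n_segs} segments, "
            f"{n_nodes} nodes)"
        )
    incoming: dict[int, list[int]] = {}
    for s in tree.segments.values():
        incoming.setdefault(s.distal_node, []).append(s.segment_id)
    if tree.root in incoming:
        raise TreeStructureError(
            f"root {tree.root} has a proximal segment {incoming[tree.root]}"
        )
    for nid in tree.nodes:
        if nid == tree.root:
            continue
        segs = incoming.get(nid, [])
        if len(segs) != 1:
            raise TreeStructureError(
                f"node {nid} has {len(segs)} proximal segments (expected 1)"
            )
    # connectivity (and hence acyclicity, given the edge count)
    seen = {tree.root}
    frontier = [tree.root]
    children: dict[int, list[int]] = {}
    for s in tree.segments.values():
        children.setdefault(s.proximal_node, []).append(s.distal_node)
    while frontier:
        frontier = [
            v for u in frontier for v in children.get(u, []) if v not in seen
        ]
        seen.update(frontier)
    if len(seen) != n_nodes:
        raise TreeStructureError("tree is not connected from the root")


# ---------------------------------------------------------------------------
# I/O

CSV_COLUMNS = [
    "segment_id",
    "proximal_node",
    "distal_node",
    "length_um",
    "mean_radius_um",
    "is_artificial",
]


def write_tree(tree: VesselTree, path: str | Path, format: str = "graphml") -> None:
    """Serialize a tree; lossless round-trip with :func:`read_tree`.

    The CSV edge-list dialect stores only topology and segment geometry
    (node coordinates are dropped and node kinds inferred on re-reading);
    GraphML keeps node coordinates and kinds.
    """
    if not tree.segments:
        raise ValueError("refusing to write a tree with no segments")
    tree.validate()
    path = Path(path)
    if format == "graphml":
        _write_graphml(tree, path)
    elif format == "csv_edgelist":
        _write_csv(tree, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_tree(path: str | Path, format: str = "graphml") -> VesselTree:
    """Read and validate a tree written by :func:`write_tree`."""
    path = Path(path)
    if format == "graphml":
        return _read_graphml(path)
    if format == "csv_edgelist":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _write_graphml(tree: VesselTree, path: Path) -> None:
    g = nx.DiGraph()
    g.graph["sample_id"] = tree.sample_id
    g.graph["group_label"] = tree.group_label
    g.graph["root"] = str(tree.root)
    for n in tree.nodes.values():
        attrs: dict[str, object] = {"kind": n.kind}
        for name, value in (("x", n.x), ("y", n.y), ("z", n.z)):
            if value is not None:
                attrs[name] = float(value)
        g.add_node(str(n.node_id), **attrs)
    for s in sorted(tree.segments.values(), key=lambda s: s.segment_id):
        attrs = {
            "segment_id": int(s.segment_id),
            "length_um": float(s.length),
            "is_artificial": bool(s.is_artificial),
        }
        if s.mean_radius is not None:
            attrs["mean_radius_um"] = float(s.mean_radius)
        g.add_edge(str(s.proximal_node), str(s.distal_node), **attrs)
    nx.write_graphml(g, path)


def _read_graphml(path: Path) -> VesselTree:
    g = nx.read_graphml(path)
    try:
        root = int(g.graph["root"])
    except KeyError as exc:
        raise TreeStructureError(f"{path}: no declared root") from exc
    nodes = [
        Node(
            node_id=int(nid),
            x=data.get("x"),
            y=data.get("y"),
            z=data.get("z"),
            kind=data.get("kind", "junction"),
        )
        for nid, data in g.nodes(data=True)
    ]
    segments = [
        Segment(
            segment_id=int(data["segment_id"]),
            proximal_node=int(u),
            distal_node=int(v),
            length=float(data["length_um"]),
            mean_radius=(
                float(data["mean_radius_um"]) if "mean_radius_um" in data else None
            ),
            is_artificial=bool(data.get("is_artificial", False)),
        )
        for u, v, data in g.edges(data=True)
    ]
    return build_tree(
        g.graph.get("sample_id", path.stem),
        g.graph.get("group_label", ""),
        nodes,
        segments,
        root,
    )


def _write_csv(tree: VesselTree, path: Path) -> None:
    rows = [
        {
            "segment_id": s.segment_id,
            "proximal_node": s.proximal_node,
            "distal_node": s.distal_node,
            "length_um": repr(float(s.length)),
            "mean_radius_um": "" if s.mean_radius is None else repr(float(s.mean_radius)),
            "is_artificial": int(s.is_artificial),
        }
        for s in sorted(tree.segments.values(), key=lambda s: s.segment_id)
    ]
    with open(path, "w") as fh:
        fh.write(f"#root={tree.root}\n")
        fh.write(f"#sample_id={tree.sample_id}\n")
        fh.write(f"#group_label={tree.group_label}\n")
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(fh, index=False)


def _read_csv(path: Path) -> VesselTree:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    if "root" not in meta:
        raise TreeStructureError(f"{path}: no '#root=' header line")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    segments = []
    node_ids: set[int] = set()
    for row in df.itertuples(index=False):
        radius = None if pd.isna(row.mean_radius_um) else float(row.mean_radius_um)
        segments.append(
            Segment(
                segment_id=int(row.segment_id),
                proximal_node=int(row.proximal_node),
                distal_node=int(row.distal_node),
                length=float(row.length_um),
                mean_radius=radius,
                is_artificial=bool(getattr(row, "is_artificial", 0)),
            )
        )
        node_ids.update((segments[-1].proximal_node, segments[-1].distal_node))
    root = int(meta["root"])
    # the CSV dialect stores no node attributes; kinds are inferred —
    # a node touched only by artificial segments is an artificial connector
    real_touch = {
        end
        for s in segments
        if not s.is_artificial
        for end in (s.proximal_node, s.distal_node)
    }
    def kind_of(nid: int) -> str:
        if nid not in real_touch:
            return "artificial"
        return "root" if nid == root else "junction"

    nodes = [Node(nid, kind=kind_of(nid)) for nid in sorted(node_ids)]
    return build_tree(meta.get("sample_id", path.stem), meta.get("group_label", ""), nodes, segments, root)


# ---------------------------------------------------------------------------
# contraction & merging


def contract_degree2(tree: VesselTree) -> VesselTree:
    """Merge chains through degree-2 nodes into single segments.

    A segment runs between two consecutive branch points, so a node with
    exactly one parent and one child segment is not a true branch point and
    the two incident segments are one vessel stretch.  The merged segment
    keeps the most proximal chain member's id; its length is the chain sum
    and its mean radius the length-weighted mean of the chain radii
    (restricted to members with a radius).  Artificial nodes and segments
    are never contracted.  Idempotent; preserves total tree length exactly.
    """
    tree.validate()
    segments = {sid: s for sid, s in tree.segments.items()}
    nodes = dict(tree.nodes)

    def degree2_node() -> int | None:
        children: dict[int, list[Segment]] = {}
        parent: dict[int, Segment] = {}
        for s in segments.values():
            children.setdefault(s.proximal_node, []).append(s)
            parent[s.distal_node] = s
        for nid, node in nodes.items():
            if nid == tree.root or node.kind == "artificial":
                continue
            kids = children.get(nid, [])
            if nid in parent and len(kids) == 1:
                if parent[nid].is_artificial or kids[0].is_artificial:
                    continue
                return nid
        return None

    while (nid := degree2_node()) is not None:
        upper = next(s for s in segments.values() if s.distal_node == nid)
        lower = next(s for s in segments.values() if s.proximal_node == nid)
        total = upper.length + lower.length
        weighted = [
            (s.length, s.mean_radius)
            for s in (upper, lower)
            if s.mean_radius is not None
        ]
        if weighted:
            wsum = sum(w for w, _ in weighted)
            radius = sum(w * r for w, r in weighted) / wsum
        else:
            radius = None
        segments.pop(lower.segment_id)
        segments[upper.segment_id] = replace(
            upper, distal_node=lower.distal_node, length=total, mean_radius=radius
        )
        nodes.pop(nid)

    out = VesselTree(tree.sample_id, tree.group_label, nodes, segments, tree.root)
    out.validate()
    return out


def merge_trees(trees: Sequence[VesselTree]) -> VesselTree:
    """Join disjoint trees under one new artificial root node.

    Mirrors the manual repair applied when a sample's arterial root is
    damaged: an artificial node is introduced and connected to each input
    root by an artificial, measurement-free segment (length 0, no radius),
    so the result is one connected tree while the repaired region
    contributes nothing to morphometric tables.  Passing a single tree
    returns it unchanged.
    """
    if not trees:
        raise ValueError("merge_trees requires at least one tree")
    if len(trees) == 1:
        return trees[0]
    all_nodes: dict[int, Node] = {}
    all_segments: dict[int, Segment] = {}
    for t in trees:
        t.validate()
        overlap = set(t.nodes) & set(all_nodes)
        if overlap:
            raise TreeStructureError(
                f"overlapping node_ids {sorted(overlap)[:5]}; re-key inputs first"
            )
        seg_overlap = set(t.segments) & set(all_segments)
        if seg_overlap:
            raise TreeStructureError(
                f"overlapping segment_ids {sorted(seg_overlap)[:5]}; re-key inputs first"
            )
        all_nodes.update(t.nodes)
        all_segments.update(t.segments)

    new_root = max(all_nodes) + 1
    all_nodes[new_root] = Node(new_root, kind="artificial")
    next_seg = max(all_segments) + 1
    for t in trees:
        all_segments[next_seg] = Segment(
            segment_id=next_seg,
            proximal_node=new_root,
            distal_node=t.root,
            length=0.0,
            mean_radius=None,
            is_artificial=True,
        )
        next_seg += 1
    merged = VesselTree(
        sample_id="+".join(t.sample_id for t in trees),
        group_label=trees[0].group_label,
        nodes=all_nodes,
        segments=all_segments,
        root=new_root,
    )
    merged.validate()
    return merged
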