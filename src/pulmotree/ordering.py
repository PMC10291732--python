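"""Position-based classification schemes for monopodial vessel trees.

Four competing conventions assign each vessel segment an integer group by
its position in the branching structure:

``generations``
    Counts the branch points passed between the tree root and the segment
    (Weibel convention: the main trunk segment is generation 0).  Suited to
    roughly symmetric dichotomous trees; in strongly monopodial trees the
    long trunk inflates the number of groups.
``horsfield_orders``
    Centripetal orders counted from the periphery: every terminal segment
    is order 1, every parent is max(child orders) + 1.
``strahler_orders``
    Like Horsfield orders but the order only increments where at least two
    children attain the running maximum, which collapses small side
    branches of a dominant trunk into few groups.
``fractal_generations``
    Diameter-aware monopodial generations: at every branch point the
    largest-diameter child continues its parent's generation provided its
    radius is at least ``alpha`` times the parent radius; all other
    children (and a dominant child that tapers below the threshold) start
    generation parent + 1.  The root is generation 1.

Artificial segments (introduced to reconnect damaged trees) are labelled
for bookkeeping with the label of the first real segment distal to them,
but they are flagged and must be excluded from all statistics; they never
create a group of their own, and branch points made of artificial segments
do not advance any ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .vessel_graph import Segment, VesselTree

__all__ = [
    "ClassificationResult",
    "generations",
    "horsfield_orders",
    "strahler_orders",
    "fractal_generations",
    "POSITIONAL_SCHEMES",
]


@dataclass
class ClassificationResult:
    """One scheme's mapping of segment_id to an integer group label."""

    scheme: str
    labels: dict[int, int]
    n_groups: int = 0
    parameters: dict = field(default_factory=dict)
    artificial_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        real = [l for sid, l in self.labels.items() if sid not in self.artificial_ids]
        self.n_groups = len(set(real))

    def measured_labels(self) -> dict[int, int]:
        """Labels restricted to real (non-artificial) segments."""
        return {
            sid: l for sid, l in self.labels.items() if sid not in self.artificial_ids
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": sorted(self.labels),
                "scheme": self.scheme,
                "label": [self.labels[sid] for sid in sorted(self.labels)],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# traversal helpers (real structure only; artificial segments are transparent)


def _real_children(tree: VesselTree, node_id: int) -> list[Segment]:
    """Non-artificial child segments at a node, following artificial
    segments through to the real subtrees they lead to."""
    out: list[Segment] = []
    for s in tree.children_of_node(node_id):
        if s.is_artificial:
            out.extend(_real_children(tree, s.distal_node))
        else:
            out.append(s)
    return sorted(out, key=lambda s: s.segment_id)


def _real_roots(tree: VesselTree) -> list[Segment]:
    """Root segments of the maximal non-artificial subtrees."""
    return _real_children(tree, tree.root)


def _propagate_artificial(tree: VesselTree, labels: dict[int, int], default: int) -> None:
    """Give artificial segments the label of their distal subtree's first
    real segment (bookkeeping only)."""

    def first_real_label(node_id: int) -> int | None:
        for s in tree.children_of_node(node_id):
            if not s.is_artificial:
                return labels[s.segment_id]
        for s in tree.children_of_node(node_id):
            if s.is_artificial:
                found = first_real_label(s.distal_node)
                if found is not None:
                    return found
        return None

    for s in tree.segments.values():
        if s.is_artificial:
            got = first_real_label(s.distal_node)
            labels[s.segment_id] = default if got is None else got


def _artificial_ids(tree: VesselTree) -> frozenset[int]:
    return frozenset(s.segment_id for s in tree.segments.values() if s.is_artificial)


# ---------------------------------------------------------------------------
# schemes


def generations(tree: VesselTree) -> ClassificationResult:
    """Centrifugal generations: branch points passed from the root.

    The most proximal segment of each real subtree is generation 0; a
    segment's generation exceeds its parent's by one exactly when the
    shared node is a branch point (two or more real children).
    """
    labels: dict[int, int] = {}

    def visit(seg: Segment, label: int) -> None:
        labels[seg.segment_id] = label
        kids = _real_children(tree, seg.distal_node)
        step = 1 if len(kids) >= 2 else 0
        for child in kids:
            visit(child, label + step)

    for root_seg in _real_roots(tree):
        visit(root_seg, 0)
    _propagate_artificial(tree, labels, default=0)
    return ClassificationResult("generations", labels, artificial_ids=_artificial_ids(tree))


def horsfield_orders(tree: VesselTree) -> ClassificationResult:
    """Centripetal Horsfield orders: leaves 1, parent = max(children) + 1."""
    labels: dict[int, int] = {}

    def visit(seg: Segment) -> int:
        kids = _real_children(tree, seg.distal_node)
        order = 1 if not kids else max(visit(c) for c in kids) + 1
        labels[seg.segment_id] = order
        return order

    for root_seg in _real_roots(tree):
        visit(root_seg)
    _propagate_artificial(tree, labels, default=1)
    return ClassificationResult("orders", labels, artificial_ids=_artificial_ids(tree))


def strahler_orders(tree: VesselTree) -> ClassificationResult:
    """Strahler orders: leaves 1; the order increments only where at least
    two children attain the running maximum (standard multifurcation rule)."""
    labels: dict[int, int] = {}

    def visit(seg: Segment) -> int:
        kids = _real_children(tree, seg.distal_node)
        if not kids:
            order = 1
        else:
            child_orders = [visit(c) for c in kids]
            m = max(child_orders)
            order = m + 1 if child_orders.count(m) >= 2 else m
        labels[seg.segment_id] = order
        return order

    for root_seg in _real_roots(tree):
        visit(root_seg)
    _propagate_artificial(tree, labels, default=1)
    return ClassificationResult("strahler", labels, artificial_ids=_artificial_ids(tree))


def fractal_generations(tree: VesselTree, alpha: float = 0.8) -> ClassificationResult:
    """Diameter-aware monopodial generations.

    The root segment of each real subtree is generation 1.  At each branch
    point the child of largest mean radius continues the parent's
    generation iff its radius is at least ``alpha`` times the parent's;
    every other child — and the dominant child when it falls below the
    threshold — starts generation parent + 1.  Radius ties are broken
    toward the smaller segment_id.
    """
    if not (alpha > 0):
        raise ValueError("alpha must be positive")
    for seg in tree.segments.values():
        if not seg.is_artificial and seg.mean_radius is None:
            raise ValueError(
                f"fractal generations require a mean_radius on every real "
                f"segment; segment {seg.segment_id} has none"
            )
    labels: dict[int, int] = {}

    def radius_of(seg: Segment) -> float:
        assert seg.mean_radius is not None
        return seg.mean_radius

    def visit(seg: Segment, label: int) -> None:
        labels[seg.segment_id] = label
        kids = _real_children(tree, seg.distal_node)
        if not kids:
            return
        parent_r = radius_of(seg)
        radii = [radius_of(c) for c in kids]
        # dominant child: largest radius, ties toward smaller segment_id
        dominant = min(
            range(len(kids)), key=lambda i: (-radii[i], kids[i].segment_id)
        )
        for i, child in enumerate(kids):
            if i == dominant and radii[i] >= alpha * parent_r:
                visit(child, label)
            else:
                visit(child, label + 1)

    for root_seg in _real_roots(tree):
        visit(root_seg, 1)
    _propagate_artificial(tree, labels, default=1)
    return ClassificationResult(
        "fractal", labels, parameters={"alpha": alpha},
        artificial_ids=_artificial_ids(tree),
    )


POSITIONAL_SCHEMES = {
    "generations": generations,
    "orders": horsfield_orders,
    "strahler": strahler_orders,
    "fractal": fractal_generations,
}
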