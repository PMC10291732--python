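"""Synthetic monopodial vessel trees, morphometry and two-group cohorts.

Rodent and rabbit pulmonary arteries branch monopodially: one long,
gradually tapering central trunk gives off many much thinner lateral
branches, each of which is itself a small monopodial tree.  The generator
reproduces that architecture with a handful of interpretable parameters:
at every branch point the trunk continues with radius scaled by
``trunk_taper`` while one lateral starts at ``lateral_ratio`` times the
trunk radius (with lognormal jitter); branches stop below ``min_radius``.

Ground-truth morphometry covaries with vessel size the way arterial walls
do: lumen = 2 * radius, wall thickness grows affinely with the lumen, and
the smooth-muscle layer count follows a saturating curve of the lumen
(1 layer in precapillary vessels up to ~10 in the main trunk).

The measurement model emulates how such data are actually acquired:
segments whose lumen falls below the imaging detection limit (~17 um for
the uCT resolution emulated here) are never observed; each visible segment
is measured in one to a few slices with multiplicative lognormal noise;
and the smooth-muscle layer count is only available for a subset of the
measured cross sections.

Cohorts consist of two groups of animals; the treated group receives
cluster-localized effects planted on ground-truth lumen quantiles
(reduced lumen in the smallest vessels, thickened wall in the largest,
extra muscle layers distally), never on fitted clusters, so that
recovering them through the analysis pipeline is a genuine test.
Everything is deterministic given the seed.

The branching rule has two regimes, mirroring how the strong monopodial
asymmetry of the central arteries relaxes toward nearly dichotomous
ramification in the periphery: the main axial trunk tapers slowly
(``trunk_taper``) and sheds thin laterals (``lateral_ratio``), while every
branch off the main trunk tapers fast (``peripheral_taper``) with
relatively large daughters (``peripheral_ratio``), producing bushy but
shallow peripheral subtrees.  A single self-similar rule cannot do both:
it pins the ratio of longest to median root-leaf path near 2, whereas the
long-trunk architecture this generator emulates requires about 3 or more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .vessel_graph import Node, Segment, VesselTree, build_tree, contract_degree2

__all__ = [
    "TreeGenConfig",
    "GroupEffects",
    "CohortConfig",
    "CohortSample",
    "generate_tree",
    "ground_truth_morphometry",
    "apply_group_effect",
    "virtual_measurement",
    "generate_cohort",
]


@dataclass(frozen=True)
class TreeGenConfig:
    """Parameters of the monopodial tree generator (lengths/radii in um).

    Defaults were calibrated once so that a generated tree matches the
    magnitudes reported for week-old rabbit lungs: roughly 300 identified
    segments, of which roughly half carry a lumen above the ~17 um
    detection limit, with strong trunk/lateral asymmetry.
    """

    seed: int = 1
    root_radius: float = 100.0
    trunk_taper: float = 0.965
    lateral_ratio: float = 0.3
    lateral_jitter_cv: float = 0.15
    min_radius: float = 5.5
    length_to_radius: float = 6.0
    lateral_spacing: float = 25.0
    peripheral_taper: float = 0.75
    peripheral_ratio: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 < self.trunk_taper < 1.0):
            raise ValueError(
                f"trunk_taper must lie in (0, 1), got {self.trunk_taper}; "
                "taper >= 1 would grow the trunk forever"
            )
        if not (0.0 < self.lateral_ratio < self.trunk_taper):
            raise ValueError("need 0 < lateral_ratio < trunk_taper")
        if not (0.0 < self.peripheral_taper < 1.0):
            raise ValueError("peripheral_taper must lie in (0, 1)")
        if not (0.0 < self.peripheral_ratio < self.peripheral_taper):
            raise ValueError("need 0 < peripheral_ratio < peripheral_taper")
        if self.min_radius <= 0:
            raise ValueError("min_radius must be positive")
        if self.root_radius <= 0 or self.length_to_radius <= 0:
            raise ValueError("root_radius and length_to_radius must be positive")


@dataclass(frozen=True)
class GroupEffects:
    """Cluster-localized group effects planted on ground-truth quantiles.

    ``lumen_effect`` multiplies the lumen by (1 - effect) for segments
    below the ``lumen_quantile`` of ground-truth lumen; ``wall_effect``
    multiplies the wall by (1 + effect) above ``wall_quantile``;
    ``layer_effect`` is added to the layer count below ``layer_quantile``.
    Quantiles are computed among segments whose ground-truth lumen is at
    least ``quantile_floor_um`` (normally the detection limit), i.e. among
    the vessels an observer could actually see, which is where the
    study-design questions live.
    """

    lumen_effect: float = 0.0
    lumen_quantile: float = 0.33
    wall_effect: float = 0.0
    wall_quantile: float = 0.67
    layer_effect: float = 0.0
    layer_quantile: float = 0.33
    quantile_floor_um: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lumen_effect", "wall_effect", "layer_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.lumen_effect < 1):
            raise ValueError("lumen_effect must lie in [0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """A two-group pilot cohort (defaults: 2 animals per group)."""

    seed: int = 1
    n_per_group: int = 2
    group_names: tuple[str, str] = ("NOX", "HYX")
    tree: TreeGenConfig = field(default_factory=TreeGenConfig)
    effects: GroupEffects = field(
        default_factory=lambda: GroupEffects(
            lumen_effect=0.2, wall_effect=0.15, layer_effect=0.6
        )
    )
    noise_cv: float = 0.05
    detection_limit: float = 17.0
    min_observations: int = 1
    max_observations: int = 3
    layer_obs_prob: float = 0.72
    layer_miscount_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tree = TreeGenConfig(**raw.pop("tree", {}))
        effects = GroupEffects(**raw.pop("effects", {}))
        if "group_names" in raw:
            raw["group_names"] = tuple(raw["group_names"])
        return cls(tree=tree, effects=effects, **raw)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "n_per_group": self.n_per_group,
            "group_names": list(self.group_names),
            "tree": {k: getattr(self.tree, k) for k in TreeGenConfig.__dataclass_fields__},
            "effects": {k: getattr(self.effects, k) for k in GroupEffects.__dataclass_fields__},
            "noise_cv": self.noise_cv,
            "detection_limit": self.detection_limit,
            "min_observations": self.min_observations,
            "max_observations": self.max_observations,
            "layer_obs_prob": self.layer_obs_prob,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# tree generation


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    raw = rng.normal(size=3)
    raw -= raw.dot(v) * v
    n = np.linalg.norm(raw)
    if n < 1e-9:  # pathological draw; retry deterministically
        return _perpendicular(v, rng)
    return raw / n


def generate_tree(
    config: TreeGenConfig, sample_id: str = "synthetic", group_label: str = ""
) -> VesselTree:
    """Grow one monopodial tree; deterministic for a given config.

    Every branch is a trunk: it advances in steps of length
    ``max(length_to_radius * radius, lateral_spacing)``, tapering by
    ``trunk_taper`` per step, and spawns one lateral of radius
    ``lateral_ratio * jitter * radius`` at each interior step; branches end
    below ``min_radius``.  Steps whose lateral would fall below
    ``min_radius`` produce no branch point and are merged into their
    neighbours, so the returned tree is already degree-2 contracted and
    carries a ground-truth (length-weighted) mean radius per segment.
    """
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.lateral_jitter_cv**2))

    segments: list[Segment] = []
    positions: dict[int, np.ndarray] = {0: np.zeros(3)}
    next_node = 1
    next_seg = 1

    # (proximal node, radius, direction, on main trunk?)
    stack: list[tuple[int, float, np.ndarray, bool]] = [
        (0, config.root_radius, np.array([0.0, 0.0, 1.0]), True)
    ]
    while stack:
        nid, radius, direction, axial = stack.pop()
        taper = config.trunk_taper if axial else config.peripheral_taper
        ratio = config.lateral_ratio if axial else config.peripheral_ratio
        while radius >= config.min_radius:
            length = max(config.length_to_radius * radius, config.lateral_spacing)
            wobble = rng.normal(scale=0.08, size=3)
            direction = _unit(direction + wobble)
            pos = positions[nid] + length * direction
            positions[next_node] = pos
            segments.append(
                Segment(
                    segment_id=next_seg,
                    proximal_node=nid,
                    distal_node=next_node,
                    length=float(length),
                    mean_radius=float(radius),
                )
            )
            next_seg += 1
            distal = next_node
            next_node += 1

            next_trunk = radius * taper
            lateral_r = radius * ratio * float(
                np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
            )
            if next_trunk >= config.min_radius and lateral_r >= config.min_radius:
                lat_dir = _unit(
                    0.9 * _perpendicular(direction, rng) + 0.45 * direction
                )
                stack.append((distal, lateral_r, lat_dir, False))
            nid, radius = distal, next_trunk

    node_objs = []
    children = {s.proximal_node for s in segments}
    for node_id, pos in positions.items():
        if node_id == 0:
            kind = "root"
        elif node_id in children:
            kind = "junction"
        else:
            kind = "endpoint"
        node_objs.append(
            Node(node_id, x=float(pos[0]), y=float(pos[1]), z=float(pos[2]), kind=kind)
        )
    tree = build_tree(sample_id, group_label, node_objs, segments, root=0)
    return contract_degree2(tree)


# ---------------------------------------------------------------------------
# ground-truth morphometry


def ground_truth_morphometry(
    tree: VesselTree,
    wall_offset: float = 2.0,
    wall_slope: float = 0.08,
    layer_max: int = 10,
    layer_halfsat: float = 150.0,
) -> pd.DataFrame:
    """Noise-free MeasurementTable from the tree's ground-truth radii.

    lumen = 2 * mean_radius; wall = wall_offset + wall_slope * lumen;
    layer_count = round(1 + (layer_max - 1) * lumen / (lumen + halfsat)),
    a monotone saturating curve between 1 and ``layer_max`` layers.
    Artificial segments (no radius) are excluded.
    """
    rows = []
    for s in sorted(tree.segments.values(), key=lambda s: s.segment_id):
        if s.is_artificial or s.mean_radius is None:
            continue
        lumen = 2.0 * s.mean_radius
        wall = wall_offset + wall_slope * lumen
        layers = round(1.0 + (layer_max - 1) * lumen / (lumen + layer_halfsat))
        rows.append(
            {
                "segment_id": s.segment_id,
                "lumen_diameter": lumen,
                "wall_thickness": wall,
                "layer_count": float(min(max(layers, 1), layer_max)),
                "n_observations": 1,
            }
        )
    return pd.DataFrame(rows)


def apply_group_effect(
    truth: pd.DataFrame, effects: GroupEffects, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant group effects on a ground-truth table.

    Returns (modified table, effect map).  The effect map has one row per
    segment with boolean columns ``lumen_affected``, ``wall_affected`` and
    ``layers_affected`` recording exactly which segments were altered (the
    ground truth against which recovery is judged).  Quantile thresholds
    are computed on the *input* lumen among segments with lumen at or above
    ``effects.quantile_floor_um``; segments below the floor are never
    altered.  Deterministic (the seed is accepted for interface symmetry).
    """
    del seed  # effects are deterministic functions of the truth table
    out = truth.copy()
    lumen = truth["lumen_diameter"].to_numpy(dtype=float)
    eligible = lumen >= effects.quantile_floor_um
    if not eligible.any():
        raise ValueError("no segment above the quantile floor")
    base = lumen[eligible]

    def below(q: float) -> np.ndarray:
        return eligible & (lumen <= np.quantile(base, q))

    def above(q: float) -> np.ndarray:
        return eligible & (lumen > np.quantile(base, q))

    lum_mask = below(effects.lumen_quantile) if effects.lumen_effect > 0 else np.zeros_like(eligible)
    wall_mask = above(effects.wall_quantile) if effects.wall_effect > 0 else np.zeros_like(eligible)
    lay_mask = below(effects.layer_quantile) if effects.layer_effect > 0 else np.zeros_like(eligible)

    out.loc[lum_mask, "lumen_diameter"] *= 1.0 - effects.lumen_effect
    out.loc[wall_mask, "wall_thickness"] *= 1.0 + effects.wall_effect
    out.loc[lay_mask, "layer_count"] += effects.layer_effect

    effect_map = pd.DataFrame(
        {
            "segment_id": truth["segment_id"].to_numpy(),
            "lumen_affected": lum_mask,
            "wall_affected": wall_mask,
            "layers_affected": lay_mask,
        }
    )
    return out, effect_map


# ---------------------------------------------------------------------------
# measurement model


def virtual_measurement(
    truth: pd.DataFrame,
    noise_cv: float = 0.05,
    detection_limit: float = 17.0,
    min_observations: int = 1,
    max_observations: int = 3,
    layer_obs_prob: float = 0.72,
    layer_miscount_prob: float = 0.2,
    seed: int = 0,
    visibility_lumen: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate raw cross-section observations from a ground-truth table.

    Segments with lumen below ``detection_limit`` are invisible and
    dropped.  By default visibility is judged on the table's own lumen;
    ``visibility_lumen`` (indexed like ``truth``) can supply a different
    caliber — e.g. the baseline, pre-pathology lumen — because which
    segments enter the tree is decided by tomographic detectability of the
    anatomy, whereas the fine-resolution microscopy measurements reflect
    the actual (possibly altered) lumen.  Each remaining segment is observed between ``min`` and
    ``max_observations`` times; per observation, the lumen diameter A and
    the outer diameter B = A_true + 2 * wall_true receive independent
    multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (B is floored at A so no observation is unphysical).  The
    layer count is recorded with probability ``layer_obs_prob`` per
    observation, emulating that cell layers can be counted on fewer cross
    sections than can be measured; a recorded count is off by one layer
    (either way, floored at 0) with probability ``layer_miscount_prob``,
    since distinguishing individual muscle layers at a boundary is
    genuinely ambiguous.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    caliber = (
        truth["lumen_diameter"] if visibility_lumen is None else visibility_lumen
    )
    visible = truth[np.asarray(caliber, dtype=float) >= detection_limit]
    rows = []
    for r in visible.itertuples(index=False):
        k = int(rng.integers(min_observations, max_observations + 1))
        b_true = r.lumen_diameter + 2.0 * r.wall_thickness
        for slice_id in range(k):
            a = r.lumen_diameter * float(np.exp(rng.normal(0.0, sigma)))
            b = b_true * float(np.exp(rng.normal(0.0, sigma)))
            b = max(b, a)
            has_layers = (not pd.isna(r.layer_count)) and (
                rng.random() < layer_obs_prob
            )
            if has_layers:
                layers = float(r.layer_count)
                if rng.random() < layer_miscount_prob:
                    layers = max(0.0, layers + (1.0 if rng.random() < 0.5 else -1.0))
            else:
                layers = np.nan
            rows.append(
                {
                    "segment_id": int(r.segment_id),
                    "slice_id": slice_id,
                    "A_um": a,
                    "B_um": b,
                    "layers": layers,
                }
            )
    return pd.DataFrame(rows, columns=["segment_id", "slice_id", "A_um", "B_um", "layers"])


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSample:
    """One synthetic animal: its tree, truth, observations and effect map."""

    sample_id: str
    group: str
    tree: VesselTree
    truth: pd.DataFrame
    observations: pd.DataFrame
    effect_map: pd.DataFrame


def generate_cohort(config: CohortConfig) -> list[CohortSample]:
    """Generate a full two-group cohort; deterministic given config.seed.

    The first group name is the untouched control; animals of the second
    group receive the configured effects on their ground truth before the
    measurement model is applied.  Per-animal randomness is drawn from
    independent substreams of the cohort seed.
    """
    master = np.random.default_rng(config.seed)
    control, treated = config.group_names
    samples: list[CohortSample] = []
    for group in config.group_names:
        for i in range(1, config.n_per_group + 1):
            tree_seed, meas_seed = (int(s) for s in master.integers(0, 2**31 - 1, size=2))
            sample_id = f"{group}{i}"
            tree = generate_tree(
                replace(config.tree, seed=tree_seed), sample_id=sample_id, group_label=group
            )
            truth = ground_truth_morphometry(tree)
            baseline_lumen = truth["lumen_diameter"].copy()
            if group == treated:
                effects = replace(
                    config.effects, quantile_floor_um=config.effects.quantile_floor_um
                    or config.detection_limit
                )
                truth, effect_map = apply_group_effect(truth, effects)
            else:
                effect_map = pd.DataFrame(
                    {
                        "segment_id": truth["segment_id"].to_numpy(),
                        "lumen_affected": False,
                        "wall_affected": False,
                        "layers_affected": False,
                    }
                )
            obs = virtual_measurement(
                truth,
                noise_cv=config.noise_cv,
                detection_limit=config.detection_limit,
                min_observations=config.min_observations,
                max_observations=config.max_observations,
                layer_obs_prob=config.layer_obs_prob,
                layer_miscount_prob=config.layer_miscount_prob,
                seed=meas_seed,
                visibility_lumen=baseline_lumen,
            )
            samples.append(CohortSample(sample_id, group, tree, truth, obs, effect_map))
    return samples
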