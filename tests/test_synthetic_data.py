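"""Monopodial tree generator, ground-truth morphometry, measurement model."""

import numpy as np
import pandas as pd
import pytest

from pulmotree.morphometry import aggregate_observations
from pulmotree.synthetic_data import (
    CohortConfig,
    GroupEffects,
    TreeGenConfig,
    apply_group_effect,
    generate_cohort,
    generate_tree,
    ground_truth_morphometry,
    virtual_measurement,
)


def leaf_path_lengths(tree):
    parent = {s.distal_node: s for s in tree.segments.values()}
    out = []
    for leaf in tree.leaf_segments():
        d, seg = 0, leaf
        while seg is not None:
            d += 1
            seg = parent.get(seg.proximal_node)
        out.append(d)
    return np.array(out)


class TestGenerateTree:
    def test_deterministic(self):
        cfg = TreeGenConfig(seed=11)
        assert generate_tree(cfg) == generate_tree(cfg)

    def test_immediate_termination_gives_single_segment(self):
        cfg = TreeGenConfig(root_radius=10.0, min_radius=9.9)
        t = generate_tree(cfg)
        assert len(t.segments) == 1

    def test_taper_at_least_one_rejected(self):
        with pytest.raises(ValueError, match="taper"):
            TreeGenConfig(trunk_taper=1.0)

    def test_default_config_segment_count_calibration(self):
        t = generate_tree(TreeGenConfig(seed=1))
        assert 240 <= len(t.segments) <= 360

    def test_monopodial_asymmetry_of_default_config(self):
        t = generate_tree(TreeGenConfig())
        depths = leaf_path_lengths(t)
        assert depths.max() >= 3 * np.median(depths)

    def test_tree_is_valid_and_contracted(self):
        t = generate_tree(TreeGenConfig(seed=5))
        t.validate()
        for nid in t.nodes:
            if nid != t.root:
                assert len(t.children_of_node(nid)) != 1


class TestGroundTruth:
    def test_formula(self):
        cfg = TreeGenConfig(root_radius=50.0, min_radius=49.0)
        t = generate_tree(cfg)
        truth = ground_truth_morphometry(t)
        assert truth.loc[0, "lumen_diameter"] == pytest.approx(100.0)
        assert truth.loc[0, "wall_thickness"] == pytest.approx(2.0 + 0.08 * 100.0)

    def test_layers_monotone_in_lumen(self):
        t = generate_tree(TreeGenConfig(seed=2))
        truth = ground_truth_morphometry(t).sort_values("lumen_diameter")
        layers = truth["layer_count"].to_numpy()
        assert np.all(np.diff(layers) >= 0)
        assert layers.min() >= 1 and layers.max() <= 10

    def test_five_segment_spreadsheet(self):
        from pulmotree.vessel_graph import Node, Segment, build_tree

        radii = [50.0, 30.0, 20.0, 10.0, 5.0]
        nodes = [Node(0, kind="root")] + [Node(i) for i in range(1, 6)]
        segs = [Segment(i, i - 1, i, 10.0, r) for i, r in enumerate(radii, start=1)]
        t = build_tree("hand", "", nodes, segs, root=0)
        truth = ground_truth_morphometry(t).set_index("segment_id")
        for i, r in enumerate(radii, start=1):
            lumen = 2 * r
            assert truth.loc[i, "lumen_diameter"] == pytest.approx(lumen)
            assert truth.loc[i, "wall_thickness"] == pytest.approx(2 + 0.08 * lumen)
            expected_layers = round(1 + 9 * lumen / (lumen + 150))
            assert truth.loc[i, "layer_count"] == expected_layers


class TestGroupEffects:
    @pytest.fixture
    def truth(self):
        t = generate_tree(TreeGenConfig(seed=3))
        return ground_truth_morphometry(t)

    def test_zero_effects_are_identity(self, truth):
        out, emap = apply_group_effect(truth, GroupEffects())
        pd.testing.assert_frame_equal(out, truth)
        assert not emap[["lumen_affected", "wall_affected", "layers_affected"]].any().any()

    def test_below_median_contract(self, truth):
        eff = GroupEffects(lumen_effect=0.2, lumen_quantile=0.5)
        out, emap = apply_group_effect(truth, eff)
        median = truth["lumen_diameter"].quantile(0.5)
        below = truth["lumen_diameter"] <= median
        assert emap["lumen_affected"].equals(below)
        changed = out["lumen_diameter"] != truth["lumen_diameter"]
        assert changed.equals(below & (truth["lumen_diameter"] > 0))

    def test_quantile_floor_restricts_eligible_population(self, truth):
        eff = GroupEffects(lumen_effect=0.2, lumen_quantile=0.33, quantile_floor_um=17.0)
        out, emap = apply_group_effect(truth, eff)
        assert not emap.loc[
            truth["lumen_diameter"] < 17.0, "lumen_affected"
        ].any()
        affected = truth.loc[emap["lumen_affected"], "lumen_diameter"]
        assert (affected >= 17.0).all()

    def test_wall_effect_applies_above_quantile(self, truth):
        eff = GroupEffects(wall_effect=0.15, wall_quantile=0.67)
        out, emap = apply_group_effect(truth, eff)
        cut = truth["lumen_diameter"].quantile(0.67)
        assert (truth.loc[emap["wall_affected"], "lumen_diameter"] > cut).all()
        ratio = out["wall_thickness"] / truth["wall_thickness"]
        assert ratio[emap["wall_affected"]].round(9).eq(1.15).all()


class TestVirtualMeasurement:
    @pytest.fixture
    def truth(self):
        return ground_truth_morphometry(generate_tree(TreeGenConfig(seed=4)))

    def test_noiseless_limit_reproduces_truth(self, truth):
        obs = virtual_measurement(
            truth, noise_cv=0.0, detection_limit=0.0,
            min_observations=2, max_observations=3,
            layer_obs_prob=1.0, layer_miscount_prob=0.0, seed=0,
        )
        table = aggregate_observations(obs).set_index("segment_id")
        ref = truth.set_index("segment_id")
        for sid in ref.index:
            assert table.loc[sid, "lumen_diameter"] == pytest.approx(ref.loc[sid, "lumen_diameter"])
            assert table.loc[sid, "wall_thickness"] == pytest.approx(ref.loc[sid, "wall_thickness"])
            assert table.loc[sid, "layer_count"] == pytest.approx(ref.loc[sid, "layer_count"])

    def test_detection_limit_filters_observations(self, truth):
        obs = virtual_measurement(truth, detection_limit=17.0, noise_cv=0.0, seed=1)
        assert (obs["A_um"] >= 17.0).all()
        visible = set(truth.loc[truth["lumen_diameter"] >= 17.0, "segment_id"])
        assert set(obs["segment_id"]) == visible

    def test_censored_fraction_monotone_in_limit(self, truth):
        fractions = []
        for limit in (0.0, 10.0, 17.0, 30.0):
            obs = virtual_measurement(truth, detection_limit=limit, seed=2)
            fractions.append(1.0 - obs["segment_id"].nunique() / len(truth))
        assert fractions == sorted(fractions)
        assert fractions[0] == 0.0

    def test_deterministic_per_seed(self, truth):
        a = virtual_measurement(truth, seed=7)
        b = virtual_measurement(truth, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_some_layer_counts_missing(self, truth):
        obs = virtual_measurement(truth, layer_obs_prob=0.7, seed=3)
        frac = obs["layers"].notna().mean()
        assert 0.5 < frac < 0.9


class TestCohort:
    def test_two_per_group_and_determinism(self):
        cfg = CohortConfig(seed=5)
        samples = generate_cohort(cfg)
        assert [s.sample_id for s in samples] == ["NOX1", "NOX2", "HYX1", "HYX2"]
        assert [s.group for s in samples] == ["NOX", "NOX", "HYX", "HYX"]
        again = generate_cohort(cfg)
        for a, b in zip(samples, again):
            assert a.tree == b.tree
            pd.testing.assert_frame_equal(a.observations, b.observations)

    def test_measured_fewer_than_identified(self):
        for s in generate_cohort(CohortConfig(seed=6)):
            n_identified = len(s.tree.segments)
            n_measured = s.observations["segment_id"].nunique()
            assert 0 < n_measured < n_identified

    def test_control_group_untouched_and_treated_affected(self):
        samples = generate_cohort(CohortConfig(seed=7))
        for s in samples:
            affected = s.effect_map[["lumen_affected", "wall_affected", "layers_affected"]]
            if s.group == "NOX":
                assert not affected.any().any()
            else:
                assert affected.any().any()

    def test_cohort_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(seed=9, effects=GroupEffects(lumen_effect=0.1))
        path = tmp_path / "cohort.yaml"
        cfg.to_yaml(path)
        assert CohortConfig.from_yaml(path) == cfg
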