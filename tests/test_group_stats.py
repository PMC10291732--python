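"""Mann-Whitney testing, effect strength and stratified group comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pulmotree.group_stats import (
    categorize_effect,
    compare_groups,
    comparison_table,
    effect_strength,
    mann_whitney,
    stars,
)
from pulmotree.ordering import ClassificationResult


def enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of labelings."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2

    u_obs = u_of(range(n))
    us = np.array([u_of(c) for c in itertools.combinations(range(n + m), n)])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitney:
    def test_extreme_small_sample(self):
        U, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert U == 0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        x = [float(v) for v in range(1, 31)]
        _, p = mann_whitney(x, list(x))
        assert p == pytest.approx(1.0, abs=0.01)

    def test_swap_invariance(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=6)
        assert mann_whitney(x, y) == pytest.approx(mann_whitney(y, x))

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(2, 8))
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.uniform(-1, 1), size=m)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestEffectStrength:
    def test_quantile_oracle_values(self):
        assert effect_strength(0.05, 100) == pytest.approx(0.19600, abs=5e-6)
        assert effect_strength(1 / 3, 4) == pytest.approx(0.4837, abs=5e-5)

    def test_quadrupling_n_halves_r(self):
        for p in (0.001, 0.01, 0.04):
            assert effect_strength(p, 400) == pytest.approx(effect_strength(p, 100) / 2)

    def test_monotone_decreasing_in_p(self):
        rs = [effect_strength(p, 50) for p in (0.001, 0.01, 0.04, 0.2, 0.8)]
        assert rs == sorted(rs, reverse=True)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_p_outside_unit_interval_rejected(self, p):
        with pytest.raises(ValueError):
            effect_strength(p, 10)


class TestCategories:
    @pytest.mark.parametrize(
        "r,cat",
        [
            (0.05, "none"),
            (0.1, "weak"),
            (0.12, "weak"),
            (0.18, "weak"),
            (0.29999, "weak"),
            (0.3, "medium"),
            (0.49, "medium"),
            (0.5, "strong"),
            (0.9, "strong"),
        ],
    )
    def test_band_edges(self, r, cat):
        assert categorize_effect(r) == cat

    def test_star_convention(self):
        assert stars(0.049) == "*"
        assert stars(0.009) == "**"
        assert stars(0.05) == ""
        assert stars(None) == ""


def make_cohort_tables(rng, shift=0.0, n_per_cluster=40, clusters=3):
    """Two samples per group drawn from shared morphometric strata; group B
    optionally shifted in lumen within the smallest stratum."""
    centers = [(150.0, 16.0, 8.0), (70.0, 8.0, 4.0), (25.0, 3.0, 2.0)][:clusters]
    tables, assignments, groups = {}, {}, {}
    for g, group in enumerate(("A", "B")):
        for s in range(2):
            name = f"{group}{s}"
            rows, labels = [], {}
            sid = 0
            for c, (lu, wa, la) in enumerate(centers, start=1):
                for _ in range(n_per_cluster):
                    sid += 1
                    lumen = rng.normal(lu, lu * 0.12)
                    if group == "B" and c == clusters:
                        lumen *= 1.0 - shift
                    rows.append(
                        {"segment_id": sid,
                         "lumen_diameter": abs(lumen),
                         "wall_thickness": abs(rng.normal(wa, wa * 0.15)),
                         "layer_count": max(0.0, round(rng.normal(la, 0.8))),
                         "n_observations": 1}
                    )
                    labels[sid] = c
            tables[name] = pd.DataFrame(rows)
            assignments[name] = ClassificationResult("planted", labels)
            groups[name] = group
    return tables, assignments, groups


class TestCompareGroups:
    def test_identical_groups_show_no_stars(self):
        rng = np.random.default_rng(0)
        tables, assignments, groups = make_cohort_tables(rng, shift=0.0)
        res = compare_groups(tables, assignments, groups)
        # a star at alpha=0.05 can appear by chance; with 12 tests demand
        # no more than one and no very small p
        starred = [r for r in res if r.significant]
        assert len(starred) <= 1
        assert all(r.p > 0.005 for r in res if r.p is not None)

    def test_planted_shift_found_in_its_stratum(self):
        rng = np.random.default_rng(1)
        tables, assignments, groups = make_cohort_tables(rng, shift=0.25)
        res = {(r.feature, r.stratum): r for r in compare_groups(tables, assignments, groups)}
        assert res[("lumen", "3")].p < 0.01
        assert res[("lumen", "3")].effect_r is not None
        assert res[("lumen", "1")].p > 0.05
        assert res[("lumen", "global")].p < 0.05

    def test_stratum_counts_partition_global(self):
        rng = np.random.default_rng(2)
        tables, assignments, groups = make_cohort_tables(rng)
        res = compare_groups(tables, assignments, groups)
        for feature in ("lumen", "wall", "layers"):
            rows = [r for r in res if r.feature == feature]
            glob = next(r for r in rows if r.stratum == "global")
            clusters = [r for r in rows if r.stratum != "global"]
            assert sum(r.n_a for r in clusters) == glob.n_a
            assert sum(r.n_b for r in clusters) == glob.n_b

    def test_empty_stratum_reported_not_dropped(self):
        rng = np.random.default_rng(3)
        tables, assignments, groups = make_cohort_tables(rng)
        # remove every cluster-3 segment from group A's tables
        for name in ("A0", "A1"):
            keep = [sid for sid, c in assignments[name].labels.items() if c != 3]
            tables[name] = tables[name][tables[name]["segment_id"].isin(keep)]
        res = {(r.feature, r.stratum): r for r in compare_groups(tables, assignments, groups)}
        row = res[("lumen", "3")]
        assert row.p is None and row.U is None and row.significant == ""
        assert row.n_a == 0 and row.n_b > 0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        tables, assignments, groups = make_cohort_tables(rng)
        res1 = comparison_table(compare_groups(tables, assignments, groups))
        rev = list(tables)[::-1]
        res2 = comparison_table(
            compare_groups(
                {k: tables[k] for k in rev},
                {k: assignments[k] for k in rev},
                {k: groups[k] for k in rev},
            )
        )
        pd.testing.assert_frame_equal(res1, res2)

    def test_effect_only_attached_to_significant_rows(self):
        rng = np.random.default_rng(5)
        tables, assignments, groups = make_cohort_tables(rng, shift=0.3)
        for r in compare_groups(tables, assignments, groups):
            if r.p is not None and r.p < 0.05:
                assert r.effect_r is not None
                assert r.effect_category == categorize_effect(r.effect_r)
                # N of the stratum, not of the whole dataset
                z = abs(stats.norm.ppf(r.p / 2))
                assert r.effect_r == pytest.approx(z / math.sqrt(r.n_a + r.n_b))
            else:
                assert r.effect_r is None

    def test_benjamini_hochberg_only_weakens(self):
        rng = np.random.default_rng(6)
        tables, assignments, groups = make_cohort_tables(rng, shift=0.3)
        raw = compare_groups(tables, assignments, groups)
        adj = compare_groups(tables, assignments, groups, bh_correct=True)
        for r0, r1 in zip(raw, adj):
            if r0.p is not None:
                assert r1.p >= r0.p - 1e-12


class TestTypeIError:
    def test_stratified_procedure_keeps_nominal_level(self):
        """Null cohorts: per-stratum rejection rate stays near 5% (<= 7%)."""
        rng = np.random.default_rng(99)
        counts: dict[tuple[str, str], int] = {}
        n_rep = 500
        for _ in range(n_rep):
            tables, assignments, groups = make_cohort_tables(rng, shift=0.0, n_per_cluster=25)
            for r in compare_groups(tables, assignments, groups):
                key = (r.feature, r.stratum)
                counts[key] = counts.get(key, 0) + (r.p is not None and r.p < 0.05)
        for key, c in counts.items():
            assert c / n_rep <= 0.07, f"{key}: {c / n_rep:.3f}"
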