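"""Group statistics: densities, t-tests, BH correction, level sweep."""

import numpy as np
import pandas as pd
import pytest

from somamap.atlas_map import make_tables, map_cells
from somamap.ontology import Ontology, RegionNode
from somamap.region_stats import (GroupDesign, compare_groups, density_matrix,
                                  level_sweep)
from somamap.synthetic import generate_toy_atlas
from somamap.transform import AffineTransform
from somamap.types import CellInstance


def _bh_oracle(p):
    """From-scratch BH: sort, multiply by m/rank, enforce monotonicity."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _tables_for_counts(atlas, counts_per_sample):
    """Build per-sample region tables with planted leaf counts."""
    tx = AffineTransform.identity((50.0,) * 3, 50.0)
    tables = {}
    for sid, counts in counts_per_sample.items():
        cells = []
        label = 1
        for rid, n in counts.items():
            zyx = np.argwhere(atlas.labels == rid)[0] + 0.5
            for _ in range(n):
                cells.append(CellInstance(label, tuple(zyx), 10,
                                          (int(zyx[0]), int(zyx[1]), int(zyx[2]),
                                           int(zyx[0]) + 1, int(zyx[1]) + 1,
                                           int(zyx[2]) + 1)))
                label += 1
        mapped = map_cells(cells, (50.0,) * 3, tx, atlas)
        _, region_df = make_tables(mapped, atlas, sample_id=sid)
        tables[sid] = region_df
    return tables


@pytest.fixture(scope="module")
def flat_atlas():
    return generate_toy_atlas((16, 16, 16), levels=2, seed=2)


class TestDensityMatrix:
    def test_density_and_fiber_exclusion(self, flat_atlas):
        ont = flat_atlas.ontology
        gray = [l for l in ont.leaves()
                if not (ont[l].is_ventricle or ont[l].is_fiber_tract)]
        fiber = next(l for l in ont.leaves() if ont[l].is_fiber_tract)
        tables = _tables_for_counts(flat_atlas,
                                    {"s1": {gray[0]: 10, fiber: 7}})
        m = density_matrix(tables, ont, level=ont.max_level)
        assert fiber not in m.columns
        vol = tables["s1"].set_index("region_id").loc[
            gray[0], "region_volume_mm3"]
        assert m.loc["s1", gray[0]] == pytest.approx(10 / vol)

    def test_per_total_normalization_includes_fiber_cells(self, flat_atlas):
        ont = flat_atlas.ontology
        gray = [l for l in ont.leaves()
                if not (ont[l].is_ventricle or ont[l].is_fiber_tract)]
        fiber = next(l for l in ont.leaves() if ont[l].is_fiber_tract)
        tables = _tables_for_counts(flat_atlas,
                                    {"s1": {gray[0]: 10, fiber: 90}})
        plain = density_matrix(tables, ont, ont.max_level, "per_mm3")
        normed = density_matrix(tables, ont, ont.max_level,
                                "per_mm3_per_total")
        # total = 100 cells, fiber cells included in the denominator
        assert normed.loc["s1", gray[0]] == pytest.approx(
            plain.loc["s1", gray[0]] / 100)

    def test_unknown_normalization(self, flat_atlas):
        with pytest.raises(ValueError):
            density_matrix({}, flat_atlas.ontology, 1, "bogus")


class TestCompareGroups:
    def _design(self, n_a=3, n_b=3):
        return GroupDesign([(f"a{i}", "A") for i in range(n_a)]
                           + [(f"b{i}", "B") for i in range(n_b)])

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 5, (1, 6))
        m = pd.DataFrame(np.repeat(data, 6, axis=0),
                         index=["a0", "a1", "a2", "b0", "b1", "b2"])
        out = compare_groups(m, self._design(), "A", "B")
        assert (out.t_statistic == 0).all()
        assert (out.p_value == 1).all()
        assert not out.significant.any()

    def test_twofold_difference_gives_log2fc_one(self):
        rng = np.random.default_rng(1)
        a = 10 + rng.normal(0, 1e-3, (3, 1))
        b = 20 + rng.normal(0, 1e-3, (3, 1))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=["a0", "a1", "a2", "b0", "b1", "b2"])
        out = compare_groups(m, self._design(), "B", "A")
        assert out.log2_fold_change.iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_bh_matches_oracle(self):
        rng = np.random.default_rng(2)
        n = 100
        # construct a matrix whose per-region p-values span a range
        a = rng.normal(0, 1, (4, n))
        b = rng.normal(rng.uniform(0, 2, n), 1, (4, n))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"a{i}" for i in range(4)]
                         + [f"b{i}" for i in range(4)])
        out = compare_groups(m, self._design(4, 4), "A", "B")
        assert np.allclose(out.p_adjusted, _bh_oracle(out.p_value), atol=1e-12)

    def test_group_swap_negates_fold_change(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(1, 10, (6, 5)),
                         index=["a0", "a1", "a2", "b0", "b1", "b2"])
        ab = compare_groups(m, self._design(), "A", "B")
        ba = compare_groups(m, self._design(), "B", "A")
        assert np.allclose(ab.log2_fold_change, -ba.log2_fold_change)
        assert np.allclose(ab.p_value, ba.p_value)

    def test_all_zero_region_only_changes_m(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.uniform(1, 10, (6, 4)),
                         index=["a0", "a1", "a2", "b0", "b1", "b2"])
        base = compare_groups(m, self._design(), "A", "B")
        m2 = m.copy()
        m2[99] = 0.0
        ext = compare_groups(m2, self._design(), "A", "B")
        assert np.allclose(ext.p_value[:4], base.p_value)
        # adjustment may only differ through the number of tests m
        assert np.all(ext.p_adjusted[:4] >= base.p_adjusted - 1e-12)

    def test_insufficient_samples_rejected(self):
        m = pd.DataFrame([[1.0], [2.0], [3.0]], index=["a0", "b0", "b1"])
        with pytest.raises(ValueError):
            compare_groups(m, GroupDesign([("a0", "A"), ("b0", "B"),
                                           ("b1", "B")]), "A", "B")

    def test_welch_flag_changes_statistic(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.5, (3, 1))
        b = rng.normal(1, 3.0, (5, 1))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"a{i}" for i in range(3)]
                         + [f"b{i}" for i in range(5)])
        d = GroupDesign([(f"a{i}", "A") for i in range(3)]
                        + [(f"b{i}", "B") for i in range(5)])
        w = compare_groups(m, d, "A", "B", welch=True)
        s = compare_groups(m, d, "A", "B", welch=False)
        assert w.p_value.iloc[0] != s.p_value.iloc[0]


class TestLevelSweep:
    def test_single_level_equals_compare_groups(self, flat_atlas):
        ont = flat_atlas.ontology
        gray = [l for l in ont.leaves()
                if not (ont[l].is_ventricle or ont[l].is_fiber_tract)]
        rng = np.random.default_rng(0)
        tabs = _tables_for_counts(flat_atlas, {
            f"{g}{i}": {gray[0]: int(rng.integers(5, 30)),
                        gray[1]: int(rng.integers(5, 30))}
            for g in "ab" for i in range(3)})
        design = GroupDesign([(f"a{i}", "A") for i in range(3)]
                             + [(f"b{i}", "B") for i in range(3)])
        sweep = level_sweep(tabs, ont, design, "A", "B", levels=[2])
        m = density_matrix(tabs, ont, 2)
        direct = compare_groups(m, design, "A", "B", level=2)
        assert np.allclose(sweep.p_value, direct.p_value)
        assert np.allclose(sweep.p_adjusted, direct.p_adjusted)

    def test_level1_fold_change_matches_whole_structure(self):
        # counts conserved across levels => root-level FC from summed counts
        atlas = generate_toy_atlas((16, 16, 16), levels=3, seed=4)
        ont = atlas.ontology
        gray = [l for l in ont.leaves()
                if not (ont[l].is_ventricle or ont[l].is_fiber_tract)]
        rng = np.random.default_rng(1)
        counts = {}
        for g, scale in (("a", 1), ("b", 2)):
            for i in range(3):
                counts[f"{g}{i}"] = {r: int(scale * rng.integers(20, 40))
                                     for r in gray}
        tabs = _tables_for_counts(atlas, counts)
        design = GroupDesign([(f"a{i}", "A") for i in range(3)]
                             + [(f"b{i}", "B") for i in range(3)])
        sweep = level_sweep(tabs, ont, design, "B", "A")
        root_fc = sweep[sweep.level == 1].log2_fold_change.iloc[0]
        assert root_fc == pytest.approx(1.0, abs=0.25)

    def test_leaf_significance_can_dilute_at_ancestor(self):
        """A strong effect in a small leaf need not survive aggregation into
        its (much larger) parent."""
        nodes = [
            RegionNode(1, "ROOT", "root", None, 1, (1, 1, 1)),
            RegionNode(2, "SMALL", "small", 1, 2, (2, 2, 2)),
            RegionNode(3, "BIG", "big", 1, 2, (3, 3, 3)),
        ]
        ont = Ontology(nodes)
        rng = np.random.default_rng(6)

        def table(sid, n_small):
            big_n = int(rng.integers(800, 1200))
            return pd.DataFrame({
                "region_id": [2, 3, 0], "acronym": ["SMALL", "BIG", "unassigned"],
                "level": [2, 2, 0], "n_cells": [n_small, big_n, 0],
                "region_volume_mm3": [0.01, 10.0, 0.0],
                "density_cells_per_mm3": [n_small / 0.01, big_n / 10.0, 0.0],
            })

        tabs = {f"a{i}": table(f"a{i}", int(rng.integers(10, 12)))
                for i in range(4)}
        tabs |= {f"b{i}": table(f"b{i}", int(rng.integers(30, 32)))
                 for i in range(4)}
        design = GroupDesign([(f"a{i}", "A") for i in range(4)]
                             + [(f"b{i}", "B") for i in range(4)])
        sweep = level_sweep(tabs, ont, design, "B", "A")
        leaf = sweep[(sweep.level == 2) & (sweep.region_id == 2)].iloc[0]
        root = sweep[sweep.level == 1].iloc[0]
        assert leaf.significant
        assert not root.significant


def test_bh_oracle_equivalence_large_scale():
    """Adjusted p-values agree with the from-scratch BH oracle to 1e-12."""
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(0)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 40))
        _, adj, _, _ = multipletests(p, alpha=0.1, method="fdr_bh")
        assert np.allclose(adj, _bh_oracle(p), atol=1e-12)
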