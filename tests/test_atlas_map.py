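"""Atlas registration, point transforms, cell mapping and region tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from somamap.atlas_map import (aggregate_to_level, import_point_transform,
                               make_tables, map_cells, register_affine)
from somamap.synthetic import generate_toy_atlas
from somamap.transform import AffineTransform
from somamap.types import CellInstance, ImageStack
from somamap.ventricle import downsample_iso


def _cell(label, z, y, x, vol=10):
    return CellInstance(label, (z, y, x), vol,
                        (int(z), int(y), int(x), int(z) + 1, int(y) + 1, int(x) + 1))


class TestTransformIO:
    def test_identity_roundtrip(self, tmp_path):
        tx = AffineTransform.identity((6, 1.625, 1.625), 50.0)
        tx.to_json(tmp_path / "tx.json")
        back = import_point_transform(tmp_path / "tx.json")
        assert np.allclose(back.matrix, tx.matrix)
        assert back.source_spacing_um == tx.source_spacing_um

    def test_singular_matrix_rejected(self, tmp_path):
        bad = np.zeros((3, 4))
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(bad, (1, 1, 1), 1.0)

    def test_inverse_composes_to_identity(self):
        m = np.hstack([np.diag([1.1, 0.9, 1.0]), [[3], [-2], [5.0]]])
        tx = AffineTransform(m, (2, 2, 2), 4.0)
        pts = np.random.default_rng(0).uniform(0, 50, (10, 3))
        back = tx.inverse().apply_um(tx.apply_um(pts))
        assert np.allclose(back, pts)


class TestRegistration:
    @pytest.fixture(scope="class")
    def template(self):
        atlas = generate_toy_atlas((24, 24, 24), levels=2, seed=3)
        from somamap.synthetic import generate_scene
        scene = generate_scene(atlas, upscale=2, cells_per_mm3=40.0, seed=5)
        return downsample_iso(scene.stack, 50.0)

    def test_self_registration_is_identity(self, template):
        tx = register_affine(template, template)
        assert np.allclose(tx.matrix[:, :3], np.eye(3), atol=0.02)
        assert np.all(np.abs(tx.matrix[:, 3]) < template.spacing_um[0])

    def test_known_shift_recovered(self, template):
        shifted = ndimage.shift(template.voxels.astype(np.float32),
                                (4, 0, 0), order=1)
        mov = ImageStack(np.clip(shifted, 0, 65535).astype(np.uint16),
                         template.spacing_um)
        tx = register_affine(mov, template)
        pts = np.array([[12.0, 12.0, 12.0], [8, 14, 10]])
        mapped = tx.apply_voxels(pts)
        assert np.abs(mapped - (pts - [4, 0, 0])).max() < 1.0

    def test_degenerate_image_rejected(self, template):
        flat = ImageStack(np.full((24, 24, 24), 5, np.uint16), (50,) * 3)
        with pytest.raises(ValueError):
            register_affine(flat, template)


class TestMapCells:
    def test_identity_transform_reads_label(self, toy_atlas):
        rid = toy_atlas.ontology.leaves()[0]
        z, y, x = [int(v[0]) for v in np.nonzero(toy_atlas.labels == rid)]
        tx = AffineTransform.identity((50.0,) * 3, 50.0)
        mapped = map_cells([_cell(1, z + 0.5, y + 0.5, x + 0.5)],
                           (50.0,) * 3, tx, toy_atlas)
        assert mapped[0].region_id == rid
        assert mapped[0].region_acronym == toy_atlas.ontology[rid].acronym
        assert mapped[0].region_color == toy_atlas.ontology[rid].color

    def test_out_of_bounds_is_region_zero(self, toy_atlas):
        tx = AffineTransform.identity((50.0,) * 3, 50.0)
        mapped = map_cells([_cell(1, 1000.0, 0.0, 0.0)], (50.0,) * 3, tx,
                           toy_atlas)
        assert mapped[0].region_id == 0
        assert mapped[0].region_acronym == "unassigned"

    def test_every_cell_appears_once(self, toy_atlas):
        tx = AffineTransform.identity((50.0,) * 3, 50.0)
        cells = [_cell(i + 1, 5.0 + i, 5.0, 5.0) for i in range(20)]
        mapped = map_cells(cells, (50.0,) * 3, tx, toy_atlas)
        assert [m.cell.label for m in mapped] == [c.label for c in cells]

    def test_scene_cells_recover_generating_region(self, small_scene):
        mapped = map_cells(small_scene.cells, small_scene.stack.spacing_um,
                           small_scene.atlas_transform, small_scene.atlas)
        ok = sum(m.region_id == rid for m, rid in
                 zip(mapped, small_scene.cell_regions))
        assert ok / len(mapped) >= 0.99


class TestTables:
    def test_zero_cells_zero_filled(self, toy_atlas):
        cells_df, region_df = make_tables([], toy_atlas)
        assert len(cells_df) == 0
        assert list(cells_df.columns)  # header present
        leaves = toy_atlas.ontology.leaves()
        assert len(region_df) == len(leaves) + 1  # + unassigned row
        assert (region_df["n_cells"] == 0).all()

    def test_counts_and_density(self, toy_atlas):
        rid = toy_atlas.ontology.leaves()[0]
        zyx = np.argwhere(toy_atlas.labels == rid)[0]
        tx = AffineTransform.identity((50.0,) * 3, 50.0)
        cells = [_cell(i + 1, *(zyx + 0.5)) for i in range(10)]
        mapped = map_cells(cells, (50.0,) * 3, tx, toy_atlas)
        _, region_df = make_tables(mapped, toy_atlas)
        row = region_df[region_df.region_id == rid].iloc[0]
        assert row.n_cells == 10
        assert row.density_cells_per_mm3 == pytest.approx(
            10 / row.region_volume_mm3)
        assert region_df["n_cells"].sum() == 10

    def test_density_is_count_over_volume(self):
        atlas = generate_toy_atlas((16, 16, 16), levels=2, seed=1)
        rid = atlas.ontology.leaves()[0]
        zyx = np.argwhere(atlas.labels == rid)[0]
        tx = AffineTransform.identity((50.0,) * 3, 50.0)
        mapped = map_cells([_cell(i + 1, *(zyx + 0.5)) for i in range(10)],
                           (50.0,) * 3, tx, atlas)
        _, region_df = make_tables(mapped, atlas)
        row = region_df[region_df.region_id == rid].iloc[0]
        assert row.density_cells_per_mm3 * row.region_volume_mm3 == pytest.approx(10)


class TestAggregateToLevel:
    def test_leaf_level_is_identity(self, toy_atlas):
        _, region_df = make_tables([], toy_atlas)
        max_level = toy_atlas.ontology.max_level
        agg = aggregate_to_level(region_df, toy_atlas.ontology, max_level)
        assert set(agg.region_id) == set(region_df.region_id)

    def test_parent_sums_children(self, toy_atlas):
        ont = toy_atlas.ontology
        _, region_df = make_tables([], toy_atlas)
        # plant counts 3 and 4 in two sibling leaves
        leaves = [l for l in ont.leaves() if ont[l].level == 3][:2]
        region_df.loc[region_df.region_id == leaves[0], "n_cells"] = 3
        region_df.loc[region_df.region_id == leaves[1], "n_cells"] = 4
        agg = aggregate_to_level(region_df, ont, 2)
        parents = {ont.ancestor_at_level(l, 2) for l in leaves}
        got = agg[agg.region_id.isin(parents)]["n_cells"].sum()
        assert got == 7

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_conserved_at_every_level(self, seed):
        atlas = generate_toy_atlas((16, 16, 16),
                                   levels=int(3 + seed % 2), seed=seed)
        ont = atlas.ontology
        rng = np.random.default_rng(seed)
        _, region_df = make_tables([], atlas)
        region_df["n_cells"] = rng.integers(0, 50, len(region_df))
        total = region_df["n_cells"].sum()
        for level in range(1, ont.max_level + 1):
            agg = aggregate_to_level(region_df, ont, level)
            assert agg["n_cells"].sum() == total
            # oracle: brute-force ancestor walk per leaf
            brute = {}
            for r in region_df.itertuples():
                if r.region_id == 0:
                    brute[0] = brute.get(0, 0) + r.n_cells
                    continue
                anc = r.region_id
                while ont[anc].level > level and ont[anc].parent_id is not None:
                    anc = ont[anc].parent_id
                brute[anc] = brute.get(anc, 0) + r.n_cells
            got = dict(zip(agg.region_id, agg.n_cells))
            assert got == brute

    def test_invalid_level(self, toy_atlas):
        _, region_df = make_tables([], toy_atlas)
        with pytest.raises(ValueError):
            aggregate_to_level(region_df, toy_atlas.ontology, 99)
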