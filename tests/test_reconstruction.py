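import numpy as np
import pytest

from ttomo import (
    BrainMask,
    DensityField,
    FractionSeriesData,
    SectioningSeries,
    VoxelGrid,
    back_project,
    build_fraction_template,
    cutoff_filter,
    reconstruct,
    section_field,
    sphere_voxel_mask,
    to_8bit,
)

from bruteforce import reconstruct_loop, section_loop, template_loop


def axis_series(axis, n_fractions, width, offset=0.0, sid=None):
    normal = [0.0, 0.0, 0.0]
    normal[axis] = 1.0
    return SectioningSeries(series_id=sid or "XYZ"[axis], normal=tuple(normal),
                            width=width, offset=offset, n_fractions=n_fractions)


def orthogonal_templates(grid, mask, n=(4, 4, 4), width=400.0):
    series = [axis_series(a, n[a], width) for a in range(3)]
    return [build_fraction_template(grid, mask, s) for s in series]


class TestBackProject:
    def test_single_fraction_gives_constant(self, cube_grid, cube_mask):
        s = axis_series(2, 1, cube_grid.extent_um[2])
        t = build_fraction_template(cube_grid, cube_mask, s)
        fld = back_project(FractionSeriesData(series_id="H", values=np.array([5.0])), t)
        assert (fld.value == 5.0).all()

    def test_indicator_of_first_fraction(self, cube_grid, cube_mask):
        s = axis_series(2, 4, 400.0)
        t = build_fraction_template(cube_grid, cube_mask, s)
        data = FractionSeriesData(series_id="H", values=np.array([1.0, 0, 0, 0]))
        fld = back_project(data, t)
        assert (fld.value == (t.fraction_of_voxel == 0).astype(float)).all()

    def test_piecewise_constant_along_normal(self, cube_grid, cube_mask):
        s = axis_series(2, 4, 400.0)
        t = build_fraction_template(cube_grid, cube_mask, s)
        rng = np.random.default_rng(0)
        data = FractionSeriesData(series_id="H", values=rng.random(4))
        fld = back_project(data, t)
        col = fld.value[3, 7, :]
        # breaks only at slab boundaries: 400 µm slabs = 4 voxels each
        for k in range(4):
            assert np.ptp(col[4 * k:4 * (k + 1)]) == 0.0

    def test_length_mismatch_rejected(self, cube_grid, cube_mask):
        s = axis_series(2, 4, 400.0)
        t = build_fraction_template(cube_grid, cube_mask, s)
        with pytest.raises(ValueError, match="values for"):
            back_project(FractionSeriesData(series_id="H", values=np.ones(3)), t)


class TestReconstruct:
    def test_uniform_field_is_conserved_exactly(self, brain200):
        """A spatially uniform expression level survives section+reconstruct."""
        mask, _, templates = brain200
        fld = DensityField(grid=mask.grid, value=np.full(mask.grid.shape, 7.5))
        data = [section_field(fld, t, mask, on_empty="zero") for t in templates]
        emap = reconstruct(data, templates)
        vals = emap.covered_values
        assert np.abs(vals - 7.5).max() / 7.5 < 1e-12

    def test_single_series_equals_back_projection(self, cube_grid, cube_mask):
        s = axis_series(2, 4, 400.0)
        t = build_fraction_template(cube_grid, cube_mask, s)
        data = FractionSeriesData(series_id="H", values=np.array([1.0, 3.0, 2.0, 4.0]))
        emap = reconstruct([data], [t])
        assert np.array_equal(emap.value, back_project(data, t).value)

    def test_sphere_phantom_matches_bruteforce_on_24cube(self):
        grid = VoxelGrid(shape=(24, 24, 24), voxel_size=100.0)
        mask = BrainMask(grid=grid, inside=np.ones(grid.shape, bool))
        templates = orthogonal_templates(grid, mask, n=(3, 3, 3), width=800.0)
        sph = sphere_voxel_mask(grid, (1200.0, 1100.0, 1300.0), 1000.0)
        fld = DensityField(grid=grid, value=sph.astype(float))
        data = [section_field(fld, t, mask) for t in templates]
        emap = reconstruct(data, templates)
        assignments = [template_loop(grid, mask.inside, t.series) for t in templates]
        ref_data = [section_loop(fld.value, a, 3) for a in assignments]
        ref = reconstruct_loop(grid, assignments, ref_data)
        for (i, j, k), v in ref.items():
            assert emap.value[i, j, k] == pytest.approx(v, rel=1e-12)

    def test_linearity_and_monotonicity(self, cube_grid, cube_mask):
        templates = orthogonal_templates(cube_grid, cube_mask)
        rng = np.random.default_rng(1)
        data_a = [FractionSeriesData(series_id=t.series.series_id, values=rng.random(4))
                  for t in templates]
        data_b = [FractionSeriesData(series_id=t.series.series_id, values=rng.random(4))
                  for t in templates]
        lhs = reconstruct(
            [FractionSeriesData(series_id=a.series_id, values=2 * a.values + b.values)
             for a, b in zip(data_a, data_b)],
            templates,
        )
        rhs = 2 * reconstruct(data_a, templates).value + reconstruct(data_b, templates).value
        assert np.allclose(lhs.value, rhs, rtol=1e-12)
        # raising one fraction value never decreases any voxel
        bumped = [FractionSeriesData(series_id=d.series_id, values=d.values.copy())
                  for d in data_a]
        bumped[1].values[2] += 1.0
        diff = reconstruct(bumped, templates).value - reconstruct(data_a, templates).value
        assert (diff >= -1e-15).all()

    def test_random_designs_match_bruteforce(self):
        """Full pipeline equals the per-voxel reference loop on small grids."""
        rng = np.random.default_rng(9)
        for trial in range(3):
            shape = tuple(rng.integers(6, 13, size=3))
            grid = VoxelGrid(shape=shape, voxel_size=100.0)
            inside = rng.random(shape) < 0.85
            inside[tuple(s // 2 for s in shape)] = True
            mask = BrainMask(grid=grid, inside=inside)
            templates = []
            for a in range(3):
                th = np.deg2rad(rng.uniform(-15, 15))
                normal = np.zeros(3)
                normal[a] = np.cos(th)
                normal[(a + 1) % 3] = np.sin(th)
                s = SectioningSeries(
                    series_id=f"T{a}", normal=tuple(normal),
                    width=float(rng.uniform(250, 500)),
                    offset=float(rng.uniform(-200, 0)), n_fractions=int(rng.integers(3, 6)),
                )
                templates.append(build_fraction_template(grid, mask, s))
            fld = DensityField(grid=grid, value=rng.random(shape))
            data = [section_field(fld, t, mask, on_empty="zero") for t in templates]
            emap = reconstruct(data, templates)
            assignments = [template_loop(grid, inside, t.series) for t in templates]
            ref_data = [
                section_loop(fld.value, a, t.series.n_fractions)
                for a, t in zip(assignments, templates)
            ]
            ref = reconstruct_loop(grid, assignments, ref_data)
            assert set(map(tuple, np.argwhere(emap.coverage.covered))) == set(ref)
            for ijk, v in ref.items():
                assert emap.value[ijk] == pytest.approx(v, rel=1e-12, abs=1e-15)

    def test_no_common_volume_rejected(self, cube_grid, cube_mask):
        lo = axis_series(2, 1, 800.0, offset=0.0)
        hi = axis_series(2, 1, 800.0, offset=800.0, sid="Z2")
        ts = [build_fraction_template(cube_grid, cube_mask, s) for s in (lo, hi)]
        data = [FractionSeriesData(series_id=s.series_id, values=np.ones(1)) for s in (lo, hi)]
        with pytest.raises(ValueError, match="no common volume"):
            reconstruct(data, ts)


class TestCutoffFilter:
    def _map(self, cube_grid, cube_mask, values):
        templates = orthogonal_templates(cube_grid, cube_mask)
        emap = reconstruct(
            [FractionSeriesData(series_id=t.series.series_id, values=np.ones(4))
             for t in templates],
            templates,
        )
        emap.value = values
        return emap

    def test_members_are_top_values(self, cube_grid, cube_mask):
        rng = np.random.default_rng(2)
        vals = rng.choice([0.0, 0.5, 1.0], size=cube_grid.shape)
        emap = self._map(cube_grid, cube_mask, vals)
        region = cutoff_filter(emap, keep_fraction=0.8)
        assert region.threshold == pytest.approx(0.8)
        assert (vals[region.member] == 1.0).all()
        assert region.n_member == (vals == 1.0).sum()
        assert emap.cutoff_threshold == pytest.approx(0.8)

    def test_small_keep_fraction_keeps_all_positive(self, cube_grid, cube_mask):
        rng = np.random.default_rng(3)
        vals = rng.random(cube_grid.shape)
        vals[vals < 0.2] = 0.0
        emap = self._map(cube_grid, cube_mask, vals)
        region = cutoff_filter(emap, keep_fraction=1e-9)
        assert region.n_member == (vals > 0).sum()

    def test_all_zero_map_rejected(self, cube_grid, cube_mask):
        emap = self._map(cube_grid, cube_mask, np.zeros(cube_grid.shape))
        with pytest.raises(ValueError, match="no signal"):
            cutoff_filter(emap)

    def test_bad_keep_fraction_rejected(self, cube_grid, cube_mask):
        emap = self._map(cube_grid, cube_mask, np.ones(cube_grid.shape))
        for kf in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                cutoff_filter(emap, keep_fraction=kf)

    def test_percentile_variant(self, cube_grid, cube_mask):
        rng = np.random.default_rng(4)
        vals = rng.random(cube_grid.shape)
        emap = self._map(cube_grid, cube_mask, vals)
        region = cutoff_filter(emap, keep_fraction=0.8, method="percentile")
        assert region.threshold == pytest.approx(np.quantile(vals, 0.8))


class TestTo8Bit:
    def _map(self, cube_grid, cube_mask, values):
        return TestCutoffFilter()._map(cube_grid, cube_mask, values)

    def test_max_maps_to_255_and_half_rounds_up(self, cube_grid, cube_mask):
        vals = np.zeros(cube_grid.shape)
        vals[0, 0, 0] = 2.0
        vals[0, 0, 1] = 1.0  # 127.5 -> rounds half away from zero -> 128
        emap = self._map(cube_grid, cube_mask, vals)
        out = to_8bit(emap)
        assert out[0, 0, 0] == 255
        assert out[0, 0, 1] == 128
        assert out.dtype == np.uint8

    def test_uniform_map_is_all_255(self, cube_grid, cube_mask):
        emap = self._map(cube_grid, cube_mask, np.full(cube_grid.shape, 0.3))
        assert (to_8bit(emap) == 255).all()

    def test_zero_map_rejected(self, cube_grid, cube_mask):
        emap = self._map(cube_grid, cube_mask, np.zeros(cube_grid.shape))
        with pytest.raises(ValueError):
            to_8bit(emap)
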