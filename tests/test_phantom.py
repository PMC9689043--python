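import numpy as np
import pytest

from lusim.phantom import (
    FieldSpectrumParams,
    Grid2D,
    MaterialMap,
    ScenarioGeometry,
    Variant,
    build_phantom,
    field_from_modes,
    generate_random_field,
    ldz_mask_for,
    ldz_material,
    make_grid,
    muscle_material,
)


@pytest.fixture
def grid():
    return Grid2D(nx=80, ny=60, dx=2e-4, dy=2e-4, x0=-8e-3, y0=0.0)


class TestRandomField:
    def test_single_mode_is_plain_cosine(self, grid):
        # one mode, zero phase, one full period across the grid width
        k = 1.0 / (grid.nx * grid.dx)
        values = field_from_modes(
            grid, np.array([k]), np.array([0.0]), np.array([1.0]), np.array([0.0])
        )
        expected = np.cos(2 * np.pi * k * grid.x)[:, None] * np.ones(grid.ny)
        np.testing.assert_allclose(values, expected, atol=1e-12)
        assert values.max() == pytest.approx(1.0, abs=1e-3)
        assert values.min() == pytest.approx(-1.0, abs=1e-3)

    @pytest.mark.parametrize("seed", range(12))
    def test_bounded_and_peak_normalized(self, grid, seed):
        params = FieldSpectrumParams(n_modes=60, k_min=0.0, k_max=2000.0, seed=seed)
        f = generate_random_field(grid, params)
        assert f.values.max() == pytest.approx(1.0, abs=1e-12)
        assert f.values.min() >= -1.0 - 1e-12

    def test_seed_determinism(self, grid):
        params = FieldSpectrumParams(n_modes=40, k_max=2000.0, seed=7)
        a = generate_random_field(grid, params)
        b = generate_random_field(grid, params)
        np.testing.assert_array_equal(a.values, b.values)
        c = generate_random_field(grid, FieldSpectrumParams(n_modes=40, k_max=2000.0, seed=8))
        assert not np.array_equal(a.values, c.values)

    def test_nyquist_violation_rejected(self):
        coarse = Grid2D(nx=10, ny=10, dx=1e-3, dy=1e-3)
        params = FieldSpectrumParams(n_modes=10, k_max=2000.0, seed=0)
        with pytest.raises(ValueError, match="Nyquist|too coarse"):
            generate_random_field(coarse, params)

    def test_anisotropy_stretches_horizontally(self, grid):
        iso = generate_random_field(grid, FieldSpectrumParams(n_modes=80, k_max=2000.0, seed=3))
        aniso = generate_random_field(
            grid, FieldSpectrumParams(n_modes=80, k_max=2000.0, seed=3, anisotropy_ratio=4.0)
        )
        # lateral gradients shrink when x-wavenumbers are divided by the ratio
        gx_iso = np.abs(np.diff(iso.values, axis=0)).mean()
        gx_aniso = np.abs(np.diff(aniso.values, axis=0)).mean()
        gy_iso = np.abs(np.diff(iso.values, axis=1)).mean()
        gy_aniso = np.abs(np.diff(aniso.values, axis=1)).mean()
        assert gx_aniso < 0.5 * gx_iso
        assert gy_aniso == pytest.approx(gy_iso, rel=0.5)


class TestMaterialMaps:
    @pytest.mark.parametrize(
        "f,v_exp,d_exp",
        [(0.0, 1070.0, 715.0), (1.0, 1500.0, 1000.0), (-1.0, 640.0, 430.0)],
    )
    def test_ldz_endpoints(self, f, v_exp, d_exp):
        v, d = ldz_material(np.array([f]))
        assert v[0] == pytest.approx(v_exp)
        assert d[0] == pytest.approx(d_exp)

    @pytest.mark.parametrize(
        "G,g,v_exp,d_exp",
        [(0.0, 0.37, 1570.0, 1090.0), (10.0, 1.0, 1580.0, 1100.0), (5.0, -1.0, 1565.0, 1085.0)],
    )
    def test_muscle_endpoints(self, G, g, v_exp, d_exp):
        v, d = muscle_material(np.array([g]), G)
        assert v[0] == pytest.approx(v_exp)
        assert d[0] == pytest.approx(d_exp)

    def test_out_of_bounds_field_rejected(self):
        with pytest.raises(ValueError):
            ldz_material(np.array([1.2]))
        with pytest.raises(ValueError):
            muscle_material(np.array([-1.2]), 5.0)
        with pytest.raises(ValueError):
            muscle_material(np.array([0.0]), -1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_ldz_ranges_never_leave_bounds(self, grid, seed):
        f = generate_random_field(grid, FieldSpectrumParams(n_modes=50, k_max=2000.0, seed=seed))
        v, d = ldz_material(f)
        assert v.min() >= 640.0 - 1e-9 and v.max() <= 1500.0 + 1e-9
        assert d.min() >= 430.0 - 1e-9 and d.max() <= 1000.0 + 1e-9


class TestBuildPhantom:
    def geometry(self, **kw):
        return ScenarioGeometry.for_variant("A", **kw)

    def test_variant_a_g0(self):
        geo = self.geometry()
        grid = make_grid(geo, f0=2e6, ppw=4)  # coarse but Nyquist-safe for the default band
        mat = build_phantom(geo, grid, G=0.0, seed_ldz=1, seed_muscle=2)
        assert np.all(mat.velocity[~mat.ldz_mask] == 1570.0)
        assert np.all(mat.density[~mat.ldz_mask] == 1090.0)
        v_ldz = mat.velocity[mat.ldz_mask]
        assert v_ldz.min() >= 640.0 and v_ldz.max() <= 1500.0
        assert v_ldz.max() > 1300.0 and v_ldz.min() < 850.0  # spans most of the range

    def test_g_monotonicity_is_exact(self):
        geo = self.geometry(ldz_length=0.0)
        grid = make_grid(geo, f0=2e6, ppw=6)
        for G in (5.0, 10.0):
            mat = build_phantom(geo, grid, G=G, seed_ldz=1, seed_muscle=2)
            assert np.abs(mat.velocity - 1570.0).max() == pytest.approx(G, abs=1e-9)

    def test_degenerate_ldz_gives_pure_muscle(self):
        geo = self.geometry(ldz_length=0.0)
        grid = make_grid(geo, f0=2e6, ppw=6)
        mat = build_phantom(geo, grid, G=5.0, seed_ldz=1, seed_muscle=2)
        assert not mat.ldz_mask.any()
        assert np.abs(mat.velocity - 1570.0).max() <= 5.0

    def test_ellipse_area_matches_analytic(self):
        geo = self.geometry()
        dx = 1e-4
        grid = Grid2D(
            nx=int(geo.total_width / dx), ny=int(geo.height / dx),
            dx=dx, dy=dx, x0=-geo.total_width / 2, y0=0.0,
        )
        mask = ldz_mask_for(geo, grid)
        area = mask.sum() * dx * dx
        analytic = np.pi * 0.005 * 0.0025  # semi-axes 5 mm x 2.5 mm
        assert area == pytest.approx(analytic, rel=0.03)

    def test_ldz_outside_rectangle_rejected(self):
        geo = self.geometry(ldz_length=0.060)
        grid = make_grid(ScenarioGeometry.for_variant("A"), f0=2e6, ppw=4)
        with pytest.raises(ValueError, match="outside"):
            build_phantom(geo, grid, G=0.0, seed_ldz=1, seed_muscle=2)

    def test_bit_identical_under_same_seeds(self):
        geo = self.geometry()
        grid = make_grid(geo, f0=2e6, ppw=4)
        a = build_phantom(geo, grid, G=5.0, seed_ldz=11, seed_muscle=12)
        b = build_phantom(geo, grid, G=5.0, seed_ldz=11, seed_muscle=12)
        np.testing.assert_array_equal(a.velocity, b.velocity)
        np.testing.assert_array_equal(a.density, b.density)
        np.testing.assert_array_equal(a.ldz_mask, b.ldz_mask)

    def test_hdf5_roundtrip(self, tmp_path):
        geo = self.geometry()
        grid = make_grid(geo, f0=2e6, ppw=4)
        mat = build_phantom(geo, grid, G=5.0, seed_ldz=3, seed_muscle=4)
        path = tmp_path / "phantom.h5"
        mat.save(path)
        back = MaterialMap.load(path)
        np.testing.assert_array_equal(mat.velocity, back.velocity)
        np.testing.assert_array_equal(mat.density, back.density)
        np.testing.assert_array_equal(mat.ldz_mask, back.ldz_mask)
        assert back.grid == mat.grid
        assert back.pml_width == mat.pml_width


class TestGeometry:
    def test_variant_lengths(self):
        assert ScenarioGeometry.for_variant("A").ldz_length == pytest.approx(0.010)
        assert ScenarioGeometry.for_variant("B").ldz_length == pytest.approx(0.004)
        assert ScenarioGeometry.for_variant(Variant.NARROW).ldz_length == pytest.approx(0.001)

    def test_ellipse_touches_top_boundary(self):
        geo = ScenarioGeometry.for_variant("A")
        dx = 1e-4
        grid = Grid2D(
            nx=int(geo.total_width / dx), ny=int(geo.height / dx),
            dx=dx, dy=dx, x0=-geo.total_width / 2, y0=0.0,
        )
        mask = ldz_mask_for(geo, grid)
        assert mask[:, -1].any()      # present in the top row of cells
        assert not mask[:, 0].any()   # absent at the array face
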