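import numpy as np
import pytest

from modescan.errors import (
    DegenerateModeError,
    DomainError,
    LookupError_,
    ParseError,
    ShapeError,
)
from modescan.mode_io import (
    DisplacementGrid,
    Geometry,
    ModeSet,
    NormalMode,
    default_grid,
    displacement_filename,
    expected_mode_count,
    generate_all,
    generate_displacements,
    load_geometry,
    load_modes,
    wide_grid,
    write_geometry,
    write_modes,
)
from modescan.synthetic import generate_mode_fixture


class TestXyz:
    def test_single_atom(self, tmp_path):
        p = tmp_path / "he.xyz"
        p.write_text("1\nhelium\nHe 0.0 0.0 0.0\n")
        g = load_geometry(p)
        assert g.n_atoms == 1
        assert np.allclose(g.coords, 0.0)

    def test_count_mismatch_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("5\nx\n" + "C 0 0 0\n" * 4)
        with pytest.raises(ParseError):
            load_geometry(p)

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nx\nC 0 0 0\nC 0 zero 0\n")
        with pytest.raises(ParseError, match="line 4"):
            load_geometry(p)

    def test_round_trip_random_structure(self, tmp_path):
        rng = np.random.default_rng(41)
        g = Geometry(elements=["C"] * 10, coords=rng.uniform(-5, 5, (10, 3)), label="rand")
        p = tmp_path / "g.xyz"
        write_geometry(g, p)
        g2 = load_geometry(p)
        assert g2.elements == g.elements
        assert np.allclose(g2.coords, g.coords, atol=1e-6)


class TestModesFile:
    def test_normalization_and_original_norm(self):
        m = NormalMode.from_raw(1, 100.0, np.array([[2.0, 0.0, 0.0]]))
        assert np.allclose(m.displacement, [[1.0, 0.0, 0.0]])
        assert m.original_norm == 2.0

    def test_zero_vector_is_degenerate(self):
        with pytest.raises(DegenerateModeError):
            NormalMode.from_raw(3, 100.0, np.zeros((2, 3)))

    def test_round_trip_full_modeset(self, tmp_path):
        geom, modeset = generate_mode_fixture(n_atoms=5, n_modes=9, seed=2)
        p = tmp_path / "modes.txt"
        write_modes(modeset, p)
        loaded = load_modes(p, geom)
        assert len(loaded) == 9
        for orig, got in zip(modeset.modes, loaded.modes):
            assert np.allclose(got.displacement, orig.displacement, atol=1e-7)
            assert abs(np.sum(got.displacement**2) - 1.0) < 1e-10

    def test_truncated_block_names_mode(self, tmp_path, water):
        text = (
            "nmodes 2 natoms 3\n\n"
            "mode 1 freq 1500.0\n0 0 1\n0 0 -1\n0 0 0\n\n"
            "mode 2 freq 1600.0\n1 0 0\n0 1 0\n"
        )
        p = tmp_path / "modes.txt"
        p.write_text(text)
        with pytest.raises((ShapeError, ParseError), match="mode 2"):
            load_modes(p, water)

    def test_atom_count_mismatch(self, tmp_path, water):
        p = tmp_path / "modes.txt"
        p.write_text("nmodes 1 natoms 2\nmode 1 freq 1.0\n1 0 0\n0 1 0\n")
        with pytest.raises(ShapeError):
            load_modes(p, water)


class TestModeCount:
    @pytest.mark.parametrize(
        "n,linear,expected",
        [(31, False, 87), (2, True, 1), (84, False, 246), (3, True, 4), (3, False, 3)],
    )
    def test_counts(self, n, linear, expected):
        g = Geometry(elements=["C"] * n, coords=np.arange(3 * n, dtype=float).reshape(n, 3))
        assert expected_mode_count(g, linear) == expected

    def test_single_atom_is_domain_error(self):
        g = Geometry(elements=["He"], coords=np.zeros((1, 3)))
        with pytest.raises(DomainError):
            expected_mode_count(g, False)


class TestGrids:
    def test_default_grid_has_21_points_with_zero(self, grid21):
        assert len(grid21) == 21
        assert grid21.includes_zero
        assert np.allclose(np.diff(grid21.factors), 0.01)

    def test_wide_grid_warns(self):
        with pytest.warns(UserWarning, match="too large"):
            g = wide_grid()
        assert len(g) == 21

    def test_non_increasing_rejected(self):
        with pytest.raises(DomainError):
            DisplacementGrid(np.array([0.0, 0.0, 0.1]))


class TestDisplacements:
    def test_21_geometries_per_mode(self, diatomic_modeset, grid21):
        geoms = generate_displacements(diatomic_modeset, 1, grid21)
        assert len(geoms) == 21

    def test_zero_factor_is_bit_identical(self, diatomic_modeset, grid21):
        geoms = generate_displacements(diatomic_modeset, 1, grid21)
        k0 = int(np.argwhere(grid21.factors == 0.0)[0, 0])
        assert np.array_equal(geoms[k0].coords, diatomic_modeset.equilibrium.coords)

    def test_plus_minus_symmetry(self, diatomic_modeset, grid21):
        geoms = generate_displacements(diatomic_modeset, 1, grid21)
        eq = diatomic_modeset.equilibrium.coords
        for k in range(len(grid21) // 2):
            mean = 0.5 * (geoms[k].coords + geoms[-1 - k].coords)
            assert np.allclose(mean, eq, atol=1e-12)

    def test_linearity(self, diatomic_modeset, grid21):
        mode = diatomic_modeset.modes[0]
        eq = diatomic_modeset.equilibrium.coords
        for geom, i in zip(generate_displacements(diatomic_modeset, 1, grid21), grid21.factors):
            # one multiply-add per component: exact up to the rounding of
            # (eq + i*d) - eq, i.e. machine epsilon relative to eq
            assert np.allclose(geom.coords - eq, i * mode.displacement, rtol=0, atol=1e-14)

    def test_unknown_mode_index(self, diatomic_modeset, grid21):
        with pytest.raises(LookupError_):
            generate_displacements(diatomic_modeset, 99, grid21)


class TestBatch:
    def test_87_modes_give_1740_new_geometries(self, grid21):
        _, modeset = generate_mode_fixture(n_atoms=31, n_modes=87, seed=0)
        geoms, manifest = generate_all(modeset, grid21)
        new = [name for name in geoms if name != "equilibrium.xyz"]
        assert len(new) == 1740
        assert len(manifest) == len(geoms)
        assert manifest["file"].is_unique

    def test_small_batch(self, diatomic_modeset):
        grid = DisplacementGrid(np.array([-0.01, 0.0, 0.01]))
        geoms, manifest = generate_all(diatomic_modeset, grid)
        assert len(geoms) == 3  # 2 displaced + shared equilibrium
        assert set(manifest.columns) == {"file", "mode", "i"}

    def test_batch_writes_deterministic_manifest(self, diatomic_modeset, grid21, tmp_path):
        _, manifest = generate_all(diatomic_modeset, grid21, outdir=tmp_path)
        files = {p.name for p in tmp_path.glob("mode*.xyz")}
        factors = [f for f in grid21.factors if f != 0.0]
        assert files == {displacement_filename(1, i) for i in factors}
        # the manifest, not the file names, carries scan order: rows after the
        # equilibrium follow the grid left to right
        on_disk = __import__("pandas").read_csv(tmp_path / "manifest.csv")
        assert np.allclose(on_disk["i"].to_numpy()[1:], factors)
        assert on_disk.equals(
            manifest.assign(i=manifest["i"].astype(float))
        ) or np.allclose(on_disk["i"], manifest["i"])
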