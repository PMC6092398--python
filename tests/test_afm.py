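"""Hard-sphere surface sampling, tip dilation and structure parsing."""
import math

import numpy as np
import pytest

from kaisim.afm import (
    AtomSet,
    HeightMap,
    TipModel,
    dilate_with_tip,
    read_structure,
    sample_surface,
)


def brute_force_dilation(surface: HeightMap, tip: TipModel) -> np.ndarray:
    """Independent oracle: exhaustive max over all translations."""
    h = surface.heights
    ny, nx = h.shape
    px = surface.pixel_size
    out = np.zeros_like(h)
    ii, jj = np.mgrid[0:ny, 0:nx]
    for y in range(ny):
        for x in range(nx):
            d = np.hypot(px * (ii - y), px * (jj - x))
            out[y, x] = max(0.0, np.max(h - tip.profile(d)))
    return out


class TestSampleSurface:
    def test_single_sphere_apex(self):
        atoms = AtomSet(positions=[[0.0, 0.0, 1.0]], radii=[1.0])
        hm = sample_surface(atoms, pixel_size=0.1)
        assert hm.heights.max() == pytest.approx(2.0, abs=1e-6)

    def test_two_atoms_max_semantics(self):
        a1 = AtomSet(positions=[[0.0, 0.0, 1.0]], radii=[1.0])
        a2 = AtomSet(positions=[[5.0, 0.0, 0.5]], radii=[0.5])
        both = AtomSet(positions=np.vstack([a1.positions, a2.positions]),
                       radii=np.concatenate([a1.radii, a2.radii]))
        hm = sample_surface(both, pixel_size=0.1)
        h1 = sample_surface(a1, pixel_size=0.1, grid_origin=hm.origin,
                            grid_shape=hm.shape)
        h2 = sample_surface(a2, pixel_size=0.1, grid_origin=hm.origin,
                            grid_shape=hm.shape)
        assert np.allclose(hm.heights, np.maximum(h1.heights, h2.heights))

    def test_grid_refinement_consistency(self):
        """Shared pixels have identical heights on a 2x finer grid."""
        atoms = AtomSet(positions=[[0.0, 0.0, 0.8], [0.9, 0.3, 0.5]],
                        radii=[0.8, 0.5])
        coarse = sample_surface(atoms, pixel_size=0.2, grid_origin=(-2.0, -2.0),
                                grid_shape=(21, 21))
        fine = sample_surface(atoms, pixel_size=0.1, grid_origin=(-2.0, -2.0),
                              grid_shape=(41, 41))
        assert np.allclose(fine.heights[::2, ::2], coarse.heights, atol=1e-9)


class TestTipModel:
    def test_profile_apex_and_tangency(self):
        tip = TipModel(apex_radius=0.5, cone_half_angle_deg=10.0)
        assert tip.profile(0.0) == pytest.approx(0.0)
        theta = math.radians(10.0)
        d_t = 0.5 * math.cos(theta)
        # continuous at the sphere-cone tangency
        eps = 1e-6
        assert tip.profile(d_t - eps) == pytest.approx(tip.profile(d_t + eps), abs=1e-4)

    def test_full_angle_mode(self):
        half = TipModel(cone_half_angle_deg=10.0)
        full = TipModel(cone_half_angle_deg=20.0, angle_is_full=True)
        d = np.linspace(0, 3, 50)
        assert np.allclose(half.profile(d), full.profile(d))

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            TipModel(apex_radius=0.0)
        with pytest.raises(ValueError):
            TipModel(cone_half_angle_deg=95.0)


class TestDilation:
    def test_flat_surface_unchanged(self):
        hm = HeightMap(origin=(0, 0), pixel_size=0.1, heights=np.full((32, 32), 1.5))
        out = dilate_with_tip(hm, TipModel())
        assert np.allclose(out.heights, 1.5)

    def test_extensive_and_monotone(self, rng):
        h1 = np.abs(rng.normal(1.0, 0.3, (40, 40)))
        h2 = h1 + np.abs(rng.normal(0.2, 0.1, (40, 40)))
        tip = TipModel()
        d1 = dilate_with_tip(HeightMap((0, 0), 0.1, h1), tip).heights
        d2 = dilate_with_tip(HeightMap((0, 0), 0.1, h2), tip).heights
        assert (d1 >= h1 - 1e-12).all()  # extensivity
        assert (d2 >= d1 - 1e-12).all()  # monotonicity

    def test_matches_brute_force_oracle_exactly(self, rng):
        heights = np.abs(rng.normal(1.0, 0.5, (64, 64)))
        hm = HeightMap(origin=(0, 0), pixel_size=0.15, heights=heights)
        tip = TipModel(apex_radius=0.5, cone_half_angle_deg=10.0)
        fast = dilate_with_tip(hm, tip).heights
        slow = brute_force_dilation(hm, tip)
        assert np.array_equal(fast, slow)

    def test_sphere_sphere_analytic_profile(self):
        """Imaging a sphere of radius r with a spherical-cap tip of radius R
        gives h(x) = r + sqrt((r+R)^2 - x^2) - R near the apex."""
        r, R = 1.0, 0.5
        px = 0.02
        atoms = AtomSet(positions=[[0.0, 0.0, r]], radii=[r])
        surface = sample_surface(atoms, pixel_size=px, padding=1.5)
        image = dilate_with_tip(surface, TipModel(apex_radius=R))
        iy = int(round((0.0 - surface.origin[1]) / px))
        jx0 = int(round((0.0 - surface.origin[0]) / px))
        for dx_pix in range(0, int(0.5 * (r + R) / px)):
            x = dx_pix * px
            expect = r + math.sqrt((r + R) ** 2 - x * x) - R
            got = image.heights[iy, jx0 + dx_pix]
            assert got == pytest.approx(expect, abs=5e-3)

    def test_translation_equivariance(self, rng):
        atoms = AtomSet(positions=rng.uniform(2, 4, (5, 3)), radii=rng.uniform(0.3, 0.8, 5))
        origin, shape, px = (0.0, 0.0), (80, 80), 0.1
        tip = TipModel()
        base = dilate_with_tip(
            sample_surface(atoms, px, grid_origin=origin, grid_shape=shape), tip
        ).heights
        shifted_atoms = atoms.translated(dx=3 * px)
        shifted = dilate_with_tip(
            sample_surface(shifted_atoms, px, grid_origin=origin, grid_shape=shape), tip
        ).heights
        assert np.allclose(shifted[:, 3:], base[:, :-3], atol=1e-9)


PDB_FIXTURE = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1      10.000  10.000   5.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.500  10.000   5.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.000  11.400   5.000  1.00  0.00           C
ATOM      4  N   GLY A   2      20.000  20.000   8.000  1.00  0.00           N
ATOM      5  CA  GLY A   2      21.500  20.000   8.000  1.00  0.00           C
ATOM      6  SG  CYS B   1      30.000  30.000  12.000  1.00  0.00           S
END
"""


class TestReadStructure:
    @pytest.fixture
    def pdb_path(self, tmp_path):
        path = tmp_path / "synthetic_test_structure.pdb"
        path.write_text(PDB_FIXTURE)
        return path

    def test_parse_and_unit_conversion(self, pdb_path):
        atoms = read_structure(pdb_path)
        assert len(atoms) == 6
        # Angstrom -> nm: first atom at (1.0, 1.0, 0.5) nm
        assert np.allclose(atoms.positions[0], [1.0, 1.0, 0.5])
        # sulfur gets its own van der Waals radius
        assert atoms.radii[-1] == pytest.approx(0.18)

    def test_residue_range_filter(self, pdb_path):
        atoms = read_structure(pdb_path, exclude_residues=(2, 2))
        assert len(atoms) == 4  # the two GLY-2 atoms removed

    def test_chain_filter(self, pdb_path):
        atoms = read_structure(pdb_path, chains=["B"])
        assert len(atoms) == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.pdb")

    def test_image_pipeline_on_fixture(self, pdb_path):
        atoms = read_structure(pdb_path)
        surface = sample_surface(atoms, pixel_size=0.1)
        image = dilate_with_tip(surface, TipModel())
        assert (image.heights >= surface.heights - 1e-12).all()
        assert image.heights.max() >= 0.5  # atoms above the substrate
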