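"""Broad-beam dose model: beam derivation, grid computation against a scalar
oracle, mask rasterization and exact DVH order statistics."""

import numpy as np
import pytest

from ocugaze.dose import (BeamSpec, DoseGrid, DVHCurve, attribute_masks,
                          compute_dose_grid, derive_beam, dose_at_points,
                          dose_at_volume, dvh, volume_at_dose,
                          water_equivalent_depth)
from ocugaze.errors import AttributionError_, OcugazeError, TreatabilityError
from ocugaze.eye_model import StructureCloud, orient_model
from ocugaze.fixation import plane_from_angles
from ocugaze.geometry import polygon_area, signed_distance_to_polygon


@pytest.fixture(scope="module")
def oriented(small_patient):
    model, _ = orient_model(small_patient, plane_from_angles(15, 60))
    return model


@pytest.fixture(scope="module")
def beam(oriented):
    return derive_beam(oriented)


class TestDeriveBeam:
    def test_range_is_deepest_depth_plus_margin(self, oriented, beam):
        depths = water_equivalent_depth(oriented.points("target"),
                                        oriented.globe_centre, oriented.globe_radius)
        assert beam.range_mm == pytest.approx(depths.max() + 2.5, abs=1e-9)
        assert beam.modulation <= beam.range_mm

    def test_circular_target_aperture_radius(self):
        """A disk-shaped target of radius 5 with margin 2.5 gives radius 7.5."""
        from ocugaze.eye_model import build_parametric_eye

        m = build_parametric_eye(seed=5, density=0.3)
        phi = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        disk = np.column_stack([5 * np.cos(phi), 5 * np.sin(phi), np.full(120, 6.0)])
        m.structures["target"] = StructureCloud("target", disk)
        beam = derive_beam(m, lateral_margin=2.5)
        r = np.linalg.norm(beam.aperture_contour, axis=1)
        assert r.max() == pytest.approx(7.5, rel=0.01)
        assert r.min() == pytest.approx(7.5, rel=0.01)

    def test_aperture_area_matches_offset_formula(self, oriented):
        """Convex offset area = A + P*m + pi*m^2 (exact Minkowski-sum oracle)."""
        from scipy.spatial import ConvexHull

        beam = derive_beam(oriented, lateral_margin=2.5)
        hull = ConvexHull(oriented.points("target")[:, :2])
        A, P = hull.volume, hull.area  # 2D: volume=area, area=perimeter
        expected = A + P * 2.5 + np.pi * 2.5 ** 2
        got = abs(polygon_area(np.vstack([beam.aperture_contour,
                                          beam.aperture_contour[:1]])[:-1]))
        assert got == pytest.approx(expected, rel=0.01)

    def test_range_limit_raises_treatability(self, oriented):
        with pytest.raises(TreatabilityError):
            derive_beam(oriented, distal_margin=30.0)

    def test_aperture_limit_raises_treatability(self):
        big = np.array([[20.0, 0], [0, 20.0], [-20.0, 0], [0, -20.0]])
        with pytest.raises(TreatabilityError):
            BeamSpec(range_mm=20.0, modulation=10.0, aperture_contour=big)


class TestDoseGrid:
    def test_plateau_dose_at_isocentre(self, oriented, beam):
        d = dose_at_points(np.zeros((1, 3)), beam, oriented.globe_centre,
                           oriented.globe_radius)
        assert d[0] == pytest.approx(60.0, rel=0.005)

    def test_far_lateral_tail_negligible(self, oriented, beam):
        # 10 penumbra widths outside the aperture, at plateau depth
        edge = beam.aperture_contour[0]
        out = edge / np.linalg.norm(edge) * (np.linalg.norm(edge) + 20.0)
        p = np.array([[out[0], out[1], 0.0]])
        d = dose_at_points(p, beam, oriented.globe_centre, oriented.globe_radius)
        assert d[0] < 0.001 * 60.0

    def test_grid_matches_scalar_oracle(self, oriented, beam):
        """Vectorized grid dose vs unvectorized per-voxel recomputation."""
        grid = compute_dose_grid(oriented, beam, shape=(16, 16, 16), spacing=1.6)
        poly = beam.aperture_contour
        s = 1.0 / (2 * np.log(4))
        c, R = oriented.globe_centre, oriented.globe_radius
        for idx in [(0, 0, 0), (8, 8, 8), (3, 12, 7), (15, 1, 9), (10, 5, 14)]:
            p = grid.origin + (np.array(idx) + 0.5) * grid.spacing
            rho2 = (p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2
            if rho2 > R ** 2:
                expected = 0.0
            else:
                depth = c[2] + np.sqrt(R ** 2 - rho2) - p[2]
                p0 = beam.range_mm - beam.modulation
                fd = (1 / (1 + np.exp(-(depth - p0) / (beam.proximal_falloff_80_20 * s)))
                      * 1 / (1 + np.exp(-(beam.range_mm - depth)
                                        / (beam.distal_falloff_80_20 * s))))
                sd = float(signed_distance_to_polygon(p[None, :2], poly)[0])
                fl = 1 / (1 + np.exp(sd / (beam.lateral_penumbra_80_20 * s)))
                expected = 60.0 * fd * fl
            assert grid.dose[idx] == pytest.approx(expected, abs=1e-9)

    def test_dose_bounded_by_prescription(self, oriented, beam):
        grid = compute_dose_grid(oriented, beam, shape=(30, 30, 30), spacing=1.2)
        assert grid.dose.min() >= 0.0
        assert grid.dose.max() <= 1.005 * 60.0

    def test_monotone_beyond_plateau(self, oriented, beam):
        """Dose falls with depth past the distal edge and with lateral distance."""
        z = np.linspace(-beam.range_mm + 5, -30.0, 40)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        d = dose_at_points(pts, beam, oriented.globe_centre, oriented.globe_radius)
        assert np.all(np.diff(d) <= 1e-12)
        x = np.linspace(10.0, 25.0, 30)
        pts = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        d = dose_at_points(pts, beam, oriented.globe_centre, oriented.globe_radius)
        assert np.all(np.diff(d) <= 1e-12)

    def test_penumbra_shrinks_to_indicator(self, oriented):
        probe = np.array([[1.0, 0.5, 0.0], [15.0, 15.0, 0.0]])
        vals = []
        for w in (2.0, 0.5, 0.05):
            b = derive_beam(oriented, lateral_penumbra_80_20=w)
            vals.append(dose_at_points(probe, b, oriented.globe_centre,
                                       oriented.globe_radius))
        inside_limit, outside_limit = vals[-1]
        assert inside_limit == pytest.approx(60.0, rel=1e-3)
        assert outside_limit == pytest.approx(0.0, abs=1e-3)


class TestMasks:
    def test_single_point_sets_its_voxel(self, small_patient):
        grid = DoseGrid(shape=(10, 10, 10), spacing=1.0, origin=np.zeros(3),
                        dose=np.zeros((10, 10, 10)))
        m = small_patient.copy()
        m.structures = {"p": StructureCloud("p", np.array([[3.5, 4.5, 5.5]]))}
        masks = attribute_masks(m, grid)
        assert masks["p"].sum() == 1
        assert masks["p"][3, 4, 5]

    def test_shift_equivariance(self, small_patient):
        grid = DoseGrid(shape=(64, 64, 64), spacing=0.7,
                        origin=np.full(3, -22.4), dose=np.zeros((64, 64, 64)))
        masks0 = attribute_masks(small_patient, grid)
        shifted = small_patient.copy()
        for cloud in shifted.structures.values():
            cloud.points = cloud.points + np.array([0.7, 0.0, 0.0])
        masks1 = attribute_masks(shifted, grid)
        np.testing.assert_array_equal(np.roll(masks0["target"], 1, axis=0),
                                      masks1["target"])

    def test_volumetric_sphere_mask_volume(self):
        """Rasterized volume of a dense spherical cloud matches 4/3 pi r^3."""
        from ocugaze.eye_model import build_parametric_eye

        r = 10.0
        h = 1.0
        # ball sampled on the voxel-centre lattice: rasterized volume must
        # reproduce the Gauss sphere approximation of 4/3 pi r^3
        ax = -15.0 + (np.arange(30) + 0.5) * h
        X, Y, Z = np.meshgrid(ax, ax, ax)
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= r]
        m = build_parametric_eye(seed=0, density=0.2)
        m.structures = {"ball": StructureCloud("ball", pts)}
        grid = DoseGrid(shape=(30, 30, 30), spacing=h, origin=np.full(3, -15.0),
                        dose=np.zeros((30, 30, 30)))
        mask = attribute_masks(m, grid)["ball"]
        assert mask.sum() == len(pts)   # one voxel per lattice point
        vol = mask.sum() * h ** 3
        assert vol == pytest.approx(4 / 3 * np.pi * r ** 3, rel=0.05)

    def test_structure_outside_grid_raises(self, small_patient):
        grid = DoseGrid(shape=(4, 4, 4), spacing=0.5, origin=np.full(3, 100.0),
                        dose=np.zeros((4, 4, 4)))
        with pytest.raises(AttributionError_):
            attribute_masks(small_patient, grid)


class TestDVH:
    def test_uniform_field_step_function(self):
        curve = DVHCurve.from_doses("s", np.full(500, 60.0))
        assert dose_at_volume(curve, 2.0) == 60.0
        assert dose_at_volume(curve, 20.0) == 60.0
        assert volume_at_dose(curve, 55.0) == 100.0
        assert volume_at_dose(curve, 60.1) == 0.0
        assert curve.volume_pct[0] == 100.0
        assert curve.volume_pct[-1] == 0.0

    def test_zero_dose(self):
        curve = DVHCurve.from_doses("s", np.zeros(100))
        assert dose_at_volume(curve, 5.0) == 0.0
        assert volume_at_dose(curve, 1.0) == 0.0

    def test_random_doses_match_sort_oracle(self):
        rng = np.random.default_rng(123)
        doses = rng.uniform(0, 70, 1000)
        curve = DVHCurve.from_doses("s", doses)
        desc = np.sort(doses)[::-1]
        for x in (2, 5, 20, 50, 97.3, 100):
            k = int(np.ceil(x / 100 * 1000))
            assert dose_at_volume(curve, x) == desc[k - 1]
        for d in (0.0, 10.0, 35.5, 69.9):
            assert volume_at_dose(curve, d) == 100.0 * np.mean(doses >= d)

    def test_argument_validation(self):
        curve = DVHCurve.from_doses("s", np.ones(10))
        with pytest.raises(OcugazeError):
            dose_at_volume(curve, 0.0)
        with pytest.raises(OcugazeError):
            volume_at_dose(curve, -1.0)

    def test_dvh_curve_monotone_non_increasing(self, oriented, beam):
        grid = compute_dose_grid(oriented, beam, shape=(40, 40, 40), spacing=0.885)
        curve = dvh(grid, "retina")
        assert np.all(np.diff(curve.volume_pct) <= 1e-12)
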