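"""Craniometric measurements: heights, widths, and distances to C."""

import numpy as np
import pytest

import abcline as ab
from abcline.craniometry import COHORT_COLUMNS, _arch_reference_distance
from abcline.errors import ParameterError, SchemaError
from abcline.phantom import CranialFrame, VascularPoints

FRAME = CranialFrame()


class TestHeightAndWidth:
    def test_height_at_dorsum_is_zero(self):
        assert ab.height_above_dorsum(np.zeros(3), FRAME) == 0.0

    def test_height_is_z_projection(self):
        assert ab.height_above_dorsum(np.array([5.0, 9.0, 12.3]), FRAME) == pytest.approx(12.3)

    def test_height_signed_below_dorsum(self):
        assert ab.height_above_dorsum(np.array([0, 0, -4.2]), FRAME) == pytest.approx(-4.2)

    def test_width_on_midline_is_zero(self):
        assert ab.width_from_midline(np.array([0.0, 10.0, -3.0]), FRAME) == 0.0

    @pytest.mark.parametrize("x", [15.7, -15.7])
    def test_width_reflection_invariant(self, x):
        assert ab.width_from_midline(np.array([x, 3.0, 3.0]), FRAME) == pytest.approx(15.7)


class TestDistanceToPolyline:
    POLY = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [20, 10, 5]], dtype=float)

    def test_on_segment_interior(self):
        assert ab.distance_to_polyline(np.array([5.0, 0, 0]), self.POLY) == pytest.approx(0.0)

    def test_perpendicular_foot(self):
        assert ab.distance_to_polyline(np.array([5.0, 0, 7.0]), self.POLY) == pytest.approx(7.0)

    def test_endpoint_clamping(self):
        # beyond the last vertex: distance to the endpoint itself
        d = ab.distance_to_polyline(np.array([23.0, 14.0, 5.0]), self.POLY)
        assert d == pytest.approx(5.0)

    def test_against_dense_sampling_oracle(self):
        """Segment projection agrees with brute-force dense sampling of
        the polyline to < 1e-3 mm."""
        rng = np.random.default_rng(21)
        # densely sample each segment with ~1e5 points overall
        seg = [
            self.POLY[i] + u[:, None] * (self.POLY[i + 1] - self.POLY[i])
            for i, u in [(i, np.linspace(0, 1, 40000)) for i in range(len(self.POLY) - 1)]
        ]
        dense = np.vstack(seg)
        for _ in range(10):
            p = rng.uniform(-5, 25, 3)
            exact = ab.distance_to_polyline(p, self.POLY)
            brute = np.min(np.linalg.norm(dense - p, axis=1))
            assert abs(exact - brute) < 1e-3

    def test_short_polyline_rejected(self):
        with pytest.raises(ParameterError):
            ab.distance_to_polyline(np.zeros(3), np.array([[1.0, 2, 3]]))


class TestMeasureAll:
    def test_mirrored_pair_gives_mirrored_records(self, default_skull):
        """On the symmetric phantom, a mirrored (A, B) pair yields equal
        measurements on the two sides."""
        A = np.array([0.0, -8.0, 4.0])
        B_r = np.array([16.0, 10.0, 6.0])
        B_l = B_r * np.array([-1.0, 1.0, 1.0])
        vessels = VascularPoints(A=A, B={"right": B_r, "left": B_l})
        recs = {}
        for side in ("right", "left"):
            traj = ab.compute_point_C(A, vessels.B[side], default_skull.mesh, validate_inside=False)
            recs[side] = ab.measure_all(default_skull, traj, side, vessels=vessels)
        for f in ("height_A_mm", "height_B_mm", "width_B_mm", "cz_mm", "cl_mm",
                  "c_vertical_mm", "c_occipitofrontal_mm"):
            assert getattr(recs["right"], f) == pytest.approx(getattr(recs["left"], f), abs=1e-9)

    def test_c_at_canthus_gives_zero_cl(self, default_skull):
        canthus = default_skull.landmarks.lateral_canthus["right"]
        traj = ab.TrajectoryResult(
            C=canthus.copy(), t_B=10.0, t_C=60.0, face_index=0,
            collinearity_residual=0.0, A=np.zeros(3), B=np.array([16.0, 10, 6]),
        )
        rec = ab.measure_all(default_skull, traj, "right")
        assert rec.cl_mm == 0.0

    def test_missing_landmark_named(self, default_skull):
        vessels = VascularPoints(A=np.zeros(3), B={"right": np.array([16.0, 10, 6])})
        traj = ab.compute_point_C(vessels.A + [0, -8, 4], vessels.B["right"],
                                  default_skull.mesh, validate_inside=False)
        with pytest.raises(SchemaError, match="B\\[left\\]"):
            ab.measure_all(default_skull, traj, "left", vessels=vessels)

    def test_full_cohort_complete(self, cohort_80):
        assert list(cohort_80.columns) == COHORT_COLUMNS
        assert len(cohort_80) == 80
        assert not cohort_80.isna().any().any()
        assert (cohort_80["width_B_mm"] >= 0).all()
        assert (cohort_80[["cz_mm", "cl_mm"]] >= 0).all().all()

    def test_distances_continuous_in_C(self, default_skull):
        """A 0.1 mm perturbation of C changes C-Z and C-L by < 0.2 mm
        (1-Lipschitz distances)."""
        rng = np.random.default_rng(3)
        arch = default_skull.landmarks.zygomatic_arch["right"]
        canthus = default_skull.landmarks.lateral_canthus["right"]
        C = np.array([50.0, 49.0, 7.5])
        for _ in range(20):
            step = rng.normal(size=3)
            step = 0.1 * step / np.linalg.norm(step)
            assert abs(
                ab.distance_to_polyline(C + step, arch) - ab.distance_to_polyline(C, arch)
            ) < 0.2
            assert abs(
                np.linalg.norm(C + step - canthus) - np.linalg.norm(C - canthus)
            ) < 0.2

    def test_midpoint_mode_uses_arch_midpoint(self, default_skull):
        arch = default_skull.landmarks.zygomatic_arch["right"]
        C = np.array([50.0, 49.0, 7.5])
        d_poly = _arch_reference_distance(C, arch, "polyline")
        d_mid = _arch_reference_distance(C, arch, "midpoint")
        assert d_mid >= d_poly  # single point can only be farther than the whole line
        with pytest.raises(ParameterError):
            _arch_reference_distance(C, arch, "geodesic")


class TestMonotoneChain:
    def test_cz_monotone_in_vessel_heights(self, default_skull):
        """C-Z distance falls as the basilar apex rises and grows as the
        carotid bifurcation rises — the geometric mechanism behind the
        reported correlation directions."""
        arch = default_skull.landmarks.zygomatic_arch["right"]
        mesh = default_skull.mesh

        def cz(hA, hB):
            traj = ab.compute_point_C(
                np.array([0.0, -8.0, hA]), np.array([15.7, 10.0, hB]), mesh,
                validate_inside=False,
            )
            return ab.distance_to_polyline(traj.C, arch)

        vals_a = [cz(h, 5.7) for h in np.arange(-5.0, 10.6, 1.0)]
        assert np.all(np.diff(vals_a) < 0)
        vals_b = [cz(4.9, h) for h in np.arange(-1.4, 15.1, 1.0)]
        assert np.all(np.diff(vals_b) > 0)
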