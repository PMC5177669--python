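"""Synthetic anatomy: skull generation, cohort sampling, voxelization."""

import numpy as np
import pytest

import abcline as ab
from abcline import geometry
from abcline.errors import ExtractionError, GenerationError, ParameterError
from abcline.phantom import calibrated_truncnorm, extract_isosurface


class TestGenerateSkull:
    def test_closed_genus_zero_surface(self, default_skull):
        mesh = default_skull.mesh
        assert mesh.euler_number == 2
        assert mesh.is_watertight
        assert mesh.volume > 0  # outward-oriented normals

    def test_landmarks_on_surface(self, default_skull):
        """All landmarks sit on the analytic ellipsoid and within 2 mm of
        the discretized surface."""
        lm = default_skull.landmarks
        center, semi = default_skull.ellipsoid
        pts = [lm.eac["right"], lm.eac["left"], lm.lateral_canthus["right"],
               lm.lateral_canthus["left"]]
        pts += list(lm.zygomatic_arch["right"]) + list(lm.zygomatic_arch["left"])
        pts = np.array(pts)
        q = np.sum(((pts - center) / semi) ** 2, axis=1)
        np.testing.assert_allclose(q, 1.0, atol=1e-12)
        d = geometry.point_triangle_distances(pts, geometry.triangles_of(default_skull.mesh))
        assert d.max() < 2.0

    def test_mirror_symmetry(self, default_skull):
        lm = default_skull.landmarks
        for name in ("eac", "lateral_canthus", "zygomatic_arch"):
            left = np.atleast_2d(getattr(lm, name)["left"])
            right = np.atleast_2d(getattr(lm, name)["right"]).copy()
            right[:, 0] = -right[:, 0]
            np.testing.assert_allclose(left, right, atol=1e-6)

    def test_arch_polyline_posterior_to_anterior(self, default_skull):
        arch = default_skull.landmarks.zygomatic_arch["right"]
        assert len(arch) >= 2
        assert np.all(np.diff(arch[:, 1]) > 0)

    def test_bit_identical_regeneration(self):
        a = ab.generate_skull(seed=0)
        b = ab.generate_skull(seed=0)
        assert np.array_equal(np.asarray(a.mesh.vertices), np.asarray(b.mesh.vertices))
        assert np.array_equal(np.asarray(a.mesh.faces), np.asarray(b.mesh.faces))

    def test_nonpositive_semiaxis_rejected(self):
        with pytest.raises(ParameterError):
            ab.generate_skull(ab.SkullParams(semi_axes=(70.0, -1.0, 65.0)))

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ParameterError):
            ab.generate_skull(ab.SkullParams(subdivisions=2))


class TestCalibratedTruncnorm:
    @pytest.mark.parametrize(
        "spec", [(4.9, 3.8, -5.0, 10.5), (5.7, 3.1, -1.4, 15.0), (15.7, 3.4, 8.4, 35.1)]
    )
    def test_truncated_moments_match_targets(self, spec):
        """The moment-matched truncated normal has exactly the requested
        mean and SD despite the asymmetric truncation."""
        mean, sd, lo, hi = spec
        dist = calibrated_truncnorm(mean, sd, lo, hi)
        m, v = dist.stats(moments="mv")
        assert float(m) == pytest.approx(mean, abs=1e-9)
        assert float(np.sqrt(v)) == pytest.approx(sd, abs=1e-9)

    def test_infeasible_sd_rejected(self):
        # an SD above the uniform bound (hi-lo)/sqrt(12) is unreachable
        with pytest.raises(ParameterError):
            calibrated_truncnorm(5.0, 1.0, 4.9, 5.1)


class TestSampleVascularPoints:
    def test_height_B_mean_recovered(self, default_skull):
        samples = ab.sample_vascular_points(default_skull, ab.CohortParams(n=2000), seed=1)
        h = np.array([s.B[s.side][2] for s in samples])
        assert abs(h.mean() - 5.7) < 0.2

    def test_narrow_truncation_bounds_respected(self, default_skull):
        params = ab.CohortParams(
            n=200,
            height_A=(5.0, 0.5, 4.0, 6.0),
            height_B=(6.0, 0.4, 5.0, 7.0),
            width_B=(15.0, 0.5, 14.0, 16.0),
        )
        samples = ab.sample_vascular_points(default_skull, params, seed=3)
        for s in samples:
            assert 4.0 <= s.A[2] <= 6.0
            assert 5.0 <= s.B[s.side][2] <= 7.0
            assert 14.0 <= abs(s.B[s.side][0]) <= 16.0

    def test_cohort_of_80_inside_skull(self, default_skull):
        samples = ab.sample_vascular_points(default_skull, ab.CohortParams(n=80), seed=7)
        assert len(samples) == 80
        pts = np.array([s.A for s in samples] + [s.B[s.side] for s in samples])
        assert default_skull.contains(pts).all()
        # A is a near-midline structure
        assert np.max(np.abs([s.A[0] for s in samples])) <= 2.0

    def test_sides_share_the_subject_apex(self, default_skull):
        samples = ab.sample_vascular_points(default_skull, ab.CohortParams(n=10), seed=0)
        by_subject = {}
        for s in samples:
            by_subject.setdefault(s.subject_id, []).append(s)
        for group in by_subject.values():
            assert len(group) == 2
            np.testing.assert_array_equal(group[0].A, group[1].A)

    def test_mirrored_sides_flag(self, default_skull):
        params = ab.CohortParams(n=4, mirror_sides=True)
        samples = ab.sample_vascular_points(default_skull, params, seed=0)
        pair = {s.side: s for s in samples if s.subject_id == 0}
        mirrored = pair["right"].B["right"].copy()
        mirrored[0] = -mirrored[0]
        np.testing.assert_allclose(pair["left"].B["left"], mirrored)

    def test_point_escaping_small_skull_raises(self):
        # vault narrower than the minimum width-of-B draw (8.4 mm): B can never fit
        tiny = ab.generate_skull(ab.SkullParams(semi_axes=(8.0, 90.0, 65.0), subdivisions=3))
        with pytest.raises(GenerationError, match="width_B|height_B"):
            ab.sample_vascular_points(tiny, ab.CohortParams(n=4), seed=0)


class TestVoxelize:
    def test_voxel_size_out_of_range(self, small_skull):
        with pytest.raises(ParameterError):
            ab.voxelize_and_extract(small_skull, 3.0)

    def test_empty_volume_extraction_error(self):
        with pytest.raises(ExtractionError):
            extract_isosurface(np.zeros((5, 5, 5), dtype=bool), 1.0)

    def test_hausdorff_within_two_voxels_and_refines(self, small_skull):
        """Rasterize/re-extract stays within 2 voxels of the source mesh,
        and halving the voxel size does not worsen the agreement."""
        coarse = ab.voxelize_and_extract(small_skull, 1.0)
        h1 = geometry.hausdorff_vertices(coarse.mesh, small_skull.mesh)
        assert h1 <= 2.0
        assert coarse.shell.sum() < coarse.occupancy.sum()

        fine = ab.voxelize_and_extract(small_skull, 0.5)
        h05 = geometry.hausdorff_vertices(fine.mesh, small_skull.mesh)
        assert h05 <= 1.0
        assert h05 <= h1
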