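"""Synthetic cranial anatomy.

Generates parametric skull phantoms — an ellipsoidal cranial vault with
named landmarks (dorsum sellae, external auditory canals, zygomatic arch
polylines, lateral canthi) — and samples vascular point pairs: the basilar
apex (point A) and the internal carotid artery bifurcation (point B).

The coordinate frame follows neurosurgical craniometry conventions: the
origin sits at the apex of the dorsum sellae, +x points to the subject's
right (lateral), +y anterior, +z superior, and the midsagittal plane is
x = 0. Heights of A and B are therefore plain z coordinates and the
lateral breadth of B is |x|. All lengths are millimetres.

Cohort sampling reproduces published population statistics: each of
height-of-A, height-of-B and width-of-B is drawn from a truncated normal
whose *truncated* mean and SD match the target values exactly (the parent
normal parameters are solved by moment matching), truncated at the
published range so no draw can fall outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import trimesh
from scipy import optimize, stats
from scipy.ndimage import binary_erosion
from skimage.measure import marching_cubes

from . import geometry
from .errors import ExtractionError, GenerationError, ParameterError

SIDES = ("right", "left")

# (mean mm, sd mm, min mm, max mm) of the published 80-sample cohort
DEFAULT_HEIGHT_A = (4.9, 3.8, -5.0, 10.5)
DEFAULT_HEIGHT_B = (5.7, 3.1, -1.4, 15.0)
DEFAULT_WIDTH_B = (15.7, 3.4, 8.4, 35.1)


@dataclass(frozen=True)
class CranialFrame:
    """Anatomical reference frame anchored at the dorsum sellae apex."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    side: str = "right"

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-12):
            raise ParameterError("frame axes must be orthonormal")
        if np.linalg.det(axes) < 0:
            raise ParameterError("frame axes must be right-handed")
        if self.side not in SIDES:
            raise ParameterError(f"side must be one of {SIDES}, got {self.side!r}")
        object.__setattr__(self, "axes", axes)


@dataclass(frozen=True)
class LandmarkSet:
    """Named cranial landmarks, per-side ones keyed 'right'/'left'."""

    dorsum_sellae: np.ndarray
    eac: Mapping[str, np.ndarray]
    lateral_canthus: Mapping[str, np.ndarray]
    zygomatic_arch: Mapping[str, np.ndarray]  # (k, 3) polylines, k >= 2
    midsagittal_normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def require(self, name: str, side: str) -> np.ndarray:
        from .errors import SchemaError

        table = getattr(self, name, None)
        if table is None or side not in table:
            raise SchemaError(f"missing landmark: {name}[{side}]")
        return np.asarray(table[side], dtype=float)


@dataclass(frozen=True)
class VascularPoints:
    """Basilar apex (A) and per-side ICA bifurcation (B) of one sample."""

    A: np.ndarray
    B: Mapping[str, np.ndarray]
    subject_id: int | None = None
    side: str | None = None


@dataclass(frozen=True)
class SkullParams:
    """Parametric skull-phantom description (all lengths mm).

    The vault is an ellipsoid with the stated semi-axes, centred
    ``center`` relative to the dorsum sellae (frame origin), so the
    skull base sits below the origin and the vertex well above it.
    Landmark placement knobs position each landmark analytically on the
    ellipsoid surface at the stated (y, z), solving for lateral x.
    """

    semi_axes: tuple[float, float, float] = (70.0, 90.0, 65.0)
    center: tuple[float, float, float] = (0.0, 0.0, 35.0)
    subdivisions: int = 5
    eac_y: float = -15.0
    eac_z: float = -10.0
    arch_z: float = -10.0
    arch_y_start: float = -10.0
    arch_y_end: float = 45.0
    arch_points: int = 5
    canthus_y: float = 55.0
    canthus_z: float = 10.0


@dataclass(frozen=True)
class AnatomyModel:
    """A complete geometric scene: mesh + frame + landmarks + vessels."""

    mesh: trimesh.Trimesh
    frame: CranialFrame
    landmarks: LandmarkSet
    vessels: VascularPoints
    params: SkullParams
    seed: int
    ellipsoid: tuple[np.ndarray, np.ndarray] | None = None  # (center, semi_axes)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inside test; analytic when the surface is a known ellipsoid."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.ellipsoid is not None:
            center, semi = self.ellipsoid
            q = np.sum(((points - center) / semi) ** 2, axis=1)
            return q < 1.0
        return geometry.points_inside(points, geometry.triangles_of(self.mesh))


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level sampling parameters.

    Distribution tuples are (mean, sd, min, max) in mm of the *sampled*
    (truncated) distribution; defaults are the published cohort values.
    Anterior-posterior offsets place A posterior and B anterior to the
    dorsum sellae, each with Gaussian jitter, approximating the
    interpeduncular vs supraclinoid positions.
    """

    n: int = 80
    height_A: tuple[float, float, float, float] = DEFAULT_HEIGHT_A
    height_B: tuple[float, float, float, float] = DEFAULT_HEIGHT_B
    width_B: tuple[float, float, float, float] = DEFAULT_WIDTH_B
    a_posterior_offset: float = -8.0
    b_anterior_offset: float = 10.0
    jitter_sd: float = 2.0
    a_lateral_sd: float = 0.7
    a_lateral_max: float = 2.0
    mirror_sides: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError(f"cohort size n must be >= 2, got {self.n}")
        for name in ("height_A", "height_B", "width_B"):
            mean, sd, lo, hi = getattr(self, name)
            if sd <= 0:
                raise ParameterError(f"{name}: sd must be > 0, got {sd}")
            if not lo < hi:
                raise ParameterError(f"{name}: min must be < max, got ({lo}, {hi})")


def _surface_x(semi_axes, center, y: float, z: float) -> float:
    """Positive x of the ellipsoid surface point at the given (y, z)."""
    a, b, c = semi_axes
    rem = 1.0 - ((y - center[1]) / b) ** 2 - ((z - center[2]) / c) ** 2
    if rem <= 0:
        raise ParameterError(
            f"landmark placement (y={y}, z={z}) lies outside the ellipsoid footprint"
        )
    return a * float(np.sqrt(rem))


def _mirror(p: np.ndarray) -> np.ndarray:
    out = np.array(p, dtype=float)
    out[0] = -out[0]
    return out


def generate_skull(params: SkullParams | None = None, seed: int = 0) -> AnatomyModel:
    """Build the watertight ellipsoidal skull phantom with landmarks.

    Deterministic: the same (params, seed) give bit-identical vertex
    arrays. ``seed`` is recorded on the model and consumed only by
    downstream stochastic stages.
    """
    params = params or SkullParams()
    semi = np.asarray(params.semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ParameterError(f"semi-axes must be positive, got {tuple(semi)}")
    if params.subdivisions < 3:
        raise ParameterError("mesh resolution must be >= 3 subdivisions")
    center = np.asarray(params.center, dtype=float)

    mesh = trimesh.creation.icosphere(subdivisions=params.subdivisions, radius=1.0)
    mesh = trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices) * semi + center,
        faces=np.asarray(mesh.faces),
        process=False,
    )

    # landmarks on the analytic surface; left side exact mirror of right
    eac_r = np.array(
        [_surface_x(semi, center, params.eac_y, params.eac_z), params.eac_y, params.eac_z]
    )
    canthus_r = np.array(
        [
            _surface_x(semi, center, params.canthus_y, params.canthus_z),
            params.canthus_y,
            params.canthus_z,
        ]
    )
    if params.arch_points < 2:
        raise ParameterError("zygomatic arch needs at least 2 points")
    arch_y = np.linspace(params.arch_y_start, params.arch_y_end, params.arch_points)
    arch_r = np.array(
        [[_surface_x(semi, center, y, params.arch_z), y, params.arch_z] for y in arch_y]
    )
    landmarks = LandmarkSet(
        dorsum_sellae=np.zeros(3),
        eac={"right": eac_r, "left": _mirror(eac_r)},
        lateral_canthus={"right": canthus_r, "left": _mirror(canthus_r)},
        zygomatic_arch={"right": arch_r, "left": np.array([_mirror(p) for p in arch_r])},
    )

    # nominal vascular pair at the cohort means (replaced by sampling)
    hA, hB, wB = DEFAULT_HEIGHT_A[0], DEFAULT_HEIGHT_B[0], DEFAULT_WIDTH_B[0]
    vessels = VascularPoints(
        A=np.array([0.0, -8.0, hA]),
        B={"right": np.array([wB, 10.0, hB]), "left": np.array([-wB, 10.0, hB])},
    )

    return AnatomyModel(
        mesh=mesh,
        frame=CranialFrame(),
        landmarks=landmarks,
        vessels=vessels,
        params=params,
        seed=seed,
        ellipsoid=(center, semi),
    )


@lru_cache(maxsize=32)
def calibrated_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Frozen truncated normal whose truncated mean/SD equal (mean, sd).

    Truncating a normal at an asymmetric range shifts its mean and
    shrinks its SD, so using the target values directly as parent
    parameters would bias the sample. Here the parent (mu, sigma) are
    solved by moment matching so the sampled distribution reproduces the
    published summary statistics exactly while every draw respects the
    published range.
    """
    if not lo < mean < hi:
        raise ParameterError(f"target mean {mean} outside truncation range ({lo}, {hi})")
    # feasibility: truncated SD is bounded above by the uniform SD on [lo, hi]
    if sd >= (hi - lo) / np.sqrt(12.0):
        raise ParameterError(
            f"target sd {sd} not attainable inside range ({lo}, {hi})"
        )

    def residual(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], tol=1e-12)
    if not sol.success:
        raise ParameterError(
            f"could not calibrate truncated normal for (mean={mean}, sd={sd}, range=({lo}, {hi}))"
        )
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return stats.truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)


def _draw_inside(draw, anatomy, param_name, max_retries=100):
    """Call ``draw()`` until the produced point lies inside the skull."""
    for _ in range(max_retries):
        point = draw()
        if anatomy.contains(point)[0]:
            return point
    raise GenerationError(
        f"sampled point stayed outside the skull after {max_retries} retries; "
        f"check parameter {param_name!r}"
    )


def sample_vascular_points(
    anatomy: AnatomyModel, cohort: CohortParams, seed: int | None = None
) -> list[VascularPoints]:
    """Sample ``cohort.n`` subject-sides of vascular point pairs.

    Samples come in subject pairs (right then left side) sharing one
    basilar apex A — the apex is a midline structure, one per patient —
    while B is drawn independently per side unless ``mirror_sides`` is
    set, in which case the left B mirrors the right. Truncated-normal
    draws are clipped nowhere: truncation is built into the distribution,
    so every draw already respects the published range.
    """
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    d_hA = calibrated_truncnorm(*cohort.height_A)
    d_hB = calibrated_truncnorm(*cohort.height_B)
    d_wB = calibrated_truncnorm(*cohort.width_B)
    # near-midline lateral jitter of A, truncated at +/- a_lateral_max
    r = cohort.a_lateral_max / cohort.a_lateral_sd
    d_xA = stats.truncnorm(-r, r, loc=0.0, scale=cohort.a_lateral_sd)

    def draw_A():
        return np.array(
            [
                float(d_xA.rvs(random_state=rng)),
                cohort.a_posterior_offset + rng.normal(0.0, cohort.jitter_sd),
                float(d_hA.rvs(random_state=rng)),
            ]
        )

    def draw_B(sign):
        return np.array(
            [
                sign * float(d_wB.rvs(random_state=rng)),
                cohort.b_anterior_offset + rng.normal(0.0, cohort.jitter_sd),
                float(d_hB.rvs(random_state=rng)),
            ]
        )

    samples: list[VascularPoints] = []
    n_subjects = (cohort.n + 1) // 2
    for subject in range(n_subjects):
        A = _draw_inside(draw_A, anatomy, "height_A")
        B_by_side: dict[str, np.ndarray] = {}
        for i, side in enumerate(SIDES):
            if cohort.mirror_sides and i == 1:
                B_by_side[side] = _mirror(B_by_side[SIDES[0]])
                continue
            sign = 1.0 if side == "right" else -1.0
            B_by_side[side] = _draw_inside(
                lambda: draw_B(sign), anatomy, "width_B/height_B"
            )

        for side in SIDES:
            if len(samples) >= cohort.n:
                break
            samples.append(
                VascularPoints(
                    A=A.copy(),
                    B={side: B_by_side[side]},
                    subject_id=subject,
                    side=side,
                )
            )
    return samples


@dataclass(frozen=True)
class VoxelizationResult:
    """Binary skull volume with grid metadata and extracted isosurface."""

    occupancy: np.ndarray  # filled head, bool (nx, ny, nz)
    shell: np.ndarray      # one-voxel surface shell, bool
    spacing: float         # isotropic voxel edge, mm
    origin: np.ndarray     # world coordinate of voxel (0,0,0) center
    mesh: trimesh.Trimesh  # isosurface of the filled volume

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing
        aff[:3, 3] = self.origin
        return aff


def extract_isosurface(
    volume: np.ndarray, spacing: float, origin: np.ndarray | None = None
) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a binary volume at level 0.5."""
    volume = np.asarray(volume)
    if not volume.any():
        raise ExtractionError("cannot extract an isosurface from an empty volume")
    try:
        verts, faces, _, _ = marching_cubes(
            volume.astype(np.float32), level=0.5, spacing=(spacing,) * 3
        )
    except (ValueError, RuntimeError) as exc:  # level outside data range etc.
        raise ExtractionError(f"isosurface extraction failed: {exc}") from exc
    if origin is not None:
        verts = verts + np.asarray(origin)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def voxelize_and_extract(
    anatomy: AnatomyModel, voxel_mm: float, margin_mm: float = 3.0
) -> VoxelizationResult:
    """Rasterize the skull surface to a binary volume and re-extract it.

    Occupancy is computed column-by-column: one ray per (x, y) voxel
    column crosses the watertight mesh, and voxels between entry/exit
    crossing pairs are filled. A one-voxel shell (occupancy minus its
    erosion) is provided alongside the filled volume; the isosurface is
    extracted from the filled volume with marching cubes.
    """
    if not 0.25 <= voxel_mm <= 2.0:
        raise ParameterError(f"voxel size must be in [0.25, 2.0] mm, got {voxel_mm}")
    tris = geometry.triangles_of(anatomy.mesh)
    lo = anatomy.mesh.bounds[0] - margin_mm
    hi = anatomy.mesh.bounds[1] + margin_mm
    shape = np.ceil((hi - lo) / voxel_mm).astype(int)
    nx, ny, nz = shape
    xs = lo[0] + (np.arange(nx) + 0.5) * voxel_mm
    ys = lo[1] + (np.arange(ny) + 0.5) * voxel_mm
    zs = lo[2] + (np.arange(nz) + 0.5) * voxel_mm

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    origins = np.column_stack(
        [gx.ravel(), gy.ravel(), np.full(gx.size, lo[2] - 1.0)]
    )
    n_col = len(origins)
    z_dir = np.array([[0.0, 0.0, 1.0]])
    z0 = lo[2] - 1.0

    def _column_crossings(orig):
        """Deduplicated z crossings per column, sorted; returns
        (column index per crossing, z, crossings-per-column counts)."""
        ray_idx, _, t = geometry.intersect_rays(
            orig, np.broadcast_to(z_dir, orig.shape), tris
        )
        order = np.lexsort((t, ray_idx))
        ray_s, t_s = ray_idx[order], t[order]
        if len(ray_s):
            dup = np.zeros(len(ray_s), dtype=bool)
            dup[1:] = (ray_s[1:] == ray_s[:-1]) & (np.diff(t_s) <= 1e-9)
            ray_s, t_s = ray_s[~dup], t_s[~dup]
        counts = np.bincount(ray_s, minlength=len(orig))
        return ray_s, z0 + t_s, counts

    ray_s, z_s, counts = _column_crossings(origins)
    odd = np.nonzero(counts % 2)[0]
    if len(odd):  # grazing hits: re-cast those columns with nudged origins
        nudge = np.array([voxel_mm * 1e-3, voxel_mm * 1.7e-3, 0.0])
        ray2, z2, counts2 = _column_crossings(origins[odd] + nudge)
        still_odd = counts2 % 2 == 1
        keep2 = ~still_odd[ray2]
        keep1 = counts[ray_s] % 2 == 0
        ray_s = np.concatenate([ray_s[keep1], odd[ray2[keep2]]])
        z_s = np.concatenate([z_s[keep1], z2[keep2]])
        order = np.lexsort((z_s, ray_s))
        ray_s, z_s = ray_s[order], z_s[order]
        counts = np.bincount(ray_s, minlength=n_col)

    # position of each crossing within its column; even = entry, odd = exit
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pos = np.arange(len(ray_s)) - starts[ray_s]
    z_in, col_in = z_s[pos % 2 == 0], ray_s[pos % 2 == 0]
    z_out = z_s[pos % 2 == 1]
    k0 = np.maximum(np.ceil((z_in - lo[2]) / voxel_mm - 0.5).astype(int), 0)
    k1 = np.minimum(np.floor((z_out - lo[2]) / voxel_mm - 0.5).astype(int), nz - 1)
    valid = k1 >= k0
    delta = np.zeros((n_col, nz + 1), dtype=np.int32)
    np.add.at(delta, (col_in[valid], k0[valid]), 1)
    np.add.at(delta, (col_in[valid], k1[valid] + 1), -1)
    occupancy = (np.cumsum(delta, axis=1)[:, :nz] > 0).reshape(nx, ny, nz)

    shell = occupancy & ~binary_erosion(occupancy)
    mesh = extract_isosurface(occupancy, voxel_mm, origin=lo + 0.5 * voxel_mm)
    return VoxelizationResult(
        occupancy=occupancy,
        shell=shell,
        spacing=voxel_mm,
        origin=lo + 0.5 * voxel_mm,
        mesh=mesh,
    )
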