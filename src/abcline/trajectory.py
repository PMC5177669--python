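"""The ABC virtual trajectory.

The access corridor to a basilar apex aneurysm is modelled as the ray
from the basilar apex (point A) through the ipsilateral ICA bifurcation
(point B); extending that ray until it exits the cranial surface defines
point C — the virtual centre of the cranial window a surgeon would need.

The ray is parameterized by arc length (unit direction), so every t is in
millimetres, with A at t = 0. Point C uses the *largest* forward
intersection parameter, i.e. the exit through the outer table, which is
robust to thin-shell meshes carrying both an inner and an outer surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .errors import GeometryError, ParameterError, UndefinedDirectionError

COLLINEARITY_TOL_MM = 1e-6
ON_SURFACE_TOL_MM = 1e-3


@dataclass(frozen=True)
class TrajectoryResult:
    """Point C with its ray parameters and diagnostics.

    ``t_B`` and ``t_C`` are arc-length ray parameters (mm) of B and C
    with A at t = 0; ``face_index`` is the intersected mesh triangle and
    ``collinearity_residual`` the distance (mm) of C from the infinite
    A-B line — a pure floating-point diagnostic that must stay below
    :data:`COLLINEARITY_TOL_MM`.
    """

    C: np.ndarray
    t_B: float
    t_C: float
    face_index: int
    collinearity_residual: float
    A: np.ndarray
    B: np.ndarray


def compute_point_C(
    A: np.ndarray, B: np.ndarray, mesh, *, validate_inside: bool = True
) -> TrajectoryResult:
    """Project the extended A->B line onto the cranium.

    Parameters
    ----------
    A, B
        Basilar apex and ICA bifurcation in frame coordinates (mm); both
        must lie strictly inside the closed mesh.
    mesh
        Watertight cranial surface (trimesh mesh).
    validate_inside
        Skip the (ray-cast) containment precondition check when the
        caller has already guaranteed it, e.g. for analytically generated
        phantoms.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    d = B - A
    norm = np.linalg.norm(d)
    if norm <= 1e-9:
        raise UndefinedDirectionError(
            f"A and B coincide (separation {norm:.3g} mm); ray direction undefined"
        )
    direction = d / norm
    tris = geometry.triangles_of(mesh)

    if validate_inside:
        inside = geometry.points_inside(np.vstack([A, B]), tris)
        if not inside[0]:
            raise ParameterError("point A lies outside the cranial mesh")
        if not inside[1]:
            raise ParameterError("point B lies outside the cranial mesh")

    ts, tri_idx = geometry.first_and_last_hits(A, direction, tris)
    if len(ts) == 0:
        # grazing configuration: nudge the origin along the ray and re-cast
        ts, tri_idx = geometry.first_and_last_hits(A + 1e-6 * direction, direction, tris)
        if len(ts) == 0:
            raise GeometryError("ray from A through B never exits the mesh")
        ts = ts + 1e-6
    t_C = float(ts[-1])
    face_index = int(tri_idx[-1])
    C = A + t_C * direction
    residual = geometry.distance_point_to_line(C, A, direction)
    return TrajectoryResult(
        C=C,
        t_B=float(norm),
        t_C=t_C,
        face_index=face_index,
        collinearity_residual=residual,
        A=A,
        B=B,
    )


def analytic_ellipsoid_intersection(
    A: np.ndarray,
    direction: np.ndarray,
    semi_axes: np.ndarray,
    center: np.ndarray | None = None,
) -> float:
    """Exit parameter of a ray from inside an axis-aligned ellipsoid.

    Solves ``||diag(1/a,1/b,1/c) (A + t d - center)||^2 = 1`` for the
    unique positive root; serves as the closed-form oracle for the mesh
    ray-casting path. ``direction`` is normalized internally so t is mm.
    """
    A = np.asarray(A, dtype=float)
    semi = np.asarray(semi_axes, dtype=float)
    c0 = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)

    p = (A - c0) / semi
    if np.dot(p, p) >= 1.0:
        raise ParameterError("ray origin must lie strictly inside the ellipsoid")
    q = d / semi
    a_coef = np.dot(q, q)
    b_coef = 2.0 * np.dot(p, q)
    c_coef = np.dot(p, p) - 1.0
    disc = b_coef * b_coef - 4.0 * a_coef * c_coef
    # origin strictly inside => two real roots of opposite sign
    return float((-b_coef + np.sqrt(disc)) / (2.0 * a_coef))


def point_C_relative_to_eac(
    result: TrajectoryResult, eac: np.ndarray
) -> tuple[float, float]:
    """Signed (vertical, occipitofrontal) offsets of C from the EAC.

    Vertical is the z difference (positive = superior), occipitofrontal
    the y difference (positive = anterior), matching how point C is
    reported relative to the ipsilateral external auditory canal.
    """
    eac = np.asarray(eac, dtype=float)
    return float(result.C[2] - eac[2]), float(result.C[1] - eac[1])
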