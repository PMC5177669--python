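"""Craniometric measurements around the ABC trajectory.

Five quantities characterize each subject-side:

* height of A — signed z of the basilar apex above the dorsum sellae;
* height of B — signed z of the ICA bifurcation above the dorsum sellae;
* width of B  — lateral breadth of the bifurcation from the midline, |x|;
* C-Z distance — from point C to the zygomatic arch (inversely reflects
  the need to remove the zygoma);
* C-L distance — from point C to the lateral canthus (inversely reflects
  the need to remove the orbital rim).

All distances are straight-line 3D Euclidean (chord) distances; heights
are signed and never floored at zero since low-set vessels legitimately
sit below the dorsum sellae. The C-Z reference is the full arch polyline
by default, with the single mid-zygomatic-point convention available as
``cz_mode='midpoint'``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError, SchemaError
from .phantom import AnatomyModel, CranialFrame, VascularPoints
from .trajectory import TrajectoryResult, point_C_relative_to_eac

COHORT_COLUMNS = [
    "subject_id",
    "side",
    "height_A_mm",
    "height_B_mm",
    "width_B_mm",
    "cz_mm",
    "cl_mm",
    "c_vertical_mm",
    "c_occipitofrontal_mm",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """All measured quantities for one side of one subject (mm)."""

    subject_id: int | str
    side: str
    height_A_mm: float
    height_B_mm: float
    width_B_mm: float
    cz_mm: float
    cl_mm: float
    c_vertical_mm: float
    c_occipitofrontal_mm: float

    def as_dict(self) -> dict:
        return asdict(self)


def height_above_dorsum(p: np.ndarray, frame: CranialFrame) -> float:
    """Signed height of a point above the dorsum sellae apex (mm)."""
    p = np.asarray(p, dtype=float)
    rel = frame.axes @ (p - frame.origin)
    return float(rel[2])


def width_from_midline(p: np.ndarray, frame: CranialFrame) -> float:
    """Perpendicular distance of a point from the midsagittal plane (mm)."""
    p = np.asarray(p, dtype=float)
    rel = frame.axes @ (p - frame.origin)
    return float(abs(rel[0]))


def distance_to_polyline(p: np.ndarray, polyline: np.ndarray) -> float:
    """Minimum distance from a point to an open polyline (mm).

    The closest point on each segment is the orthogonal projection
    clamped to the segment endpoints; the polyline distance is the
    minimum over segments.
    """
    p = np.asarray(p, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 3:
        raise ParameterError(
            f"polyline must be an (k>=2, 3) array, got shape {poly.shape}"
        )
    a = poly[:-1]
    ab = poly[1:] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    u = np.einsum("ij,ij->i", p - a, ab) / np.where(denom > 0, denom, 1.0)
    u = np.clip(u, 0.0, 1.0)
    closest = a + u[:, None] * ab
    return float(np.min(np.linalg.norm(closest - p, axis=1)))


def _arch_reference_distance(C: np.ndarray, arch: np.ndarray, mode: str) -> float:
    if mode == "polyline":
        return distance_to_polyline(C, arch)
    if mode == "midpoint":
        # mid-zygomatic point: arc-length midpoint of the arch polyline
        seg = np.linalg.norm(np.diff(arch, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        half = cum[-1] / 2.0
        i = int(np.searchsorted(cum, half)) - 1
        i = max(0, min(i, len(seg) - 1))
        frac = (half - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        mid = arch[i] + frac * (arch[i + 1] - arch[i])
        return float(np.linalg.norm(np.asarray(C) - mid))
    raise ParameterError(f"cz_mode must be 'polyline' or 'midpoint', got {mode!r}")


def measure_all(
    anatomy: AnatomyModel,
    traj: TrajectoryResult,
    side: str,
    vessels: VascularPoints | None = None,
    subject_id: int | str = 0,
    cz_mode: str = "polyline",
) -> MeasurementRecord:
    """Assemble the full measurement record for one subject-side.

    ``vessels`` defaults to the anatomy's own vascular points; pass the
    sampled pair when measuring cohort members on a shared skull.
    """
    vessels = vessels or anatomy.vessels
    if side not in vessels.B:
        raise SchemaError(f"missing vascular point: B[{side}]")
    frame = anatomy.frame
    arch = anatomy.landmarks.require("zygomatic_arch", side)
    canthus = anatomy.landmarks.require("lateral_canthus", side)
    eac = anatomy.landmarks.require("eac", side)

    vertical, occipitofrontal = point_C_relative_to_eac(traj, eac)
    return MeasurementRecord(
        subject_id=subject_id,
        side=side,
        height_A_mm=height_above_dorsum(vessels.A, frame),
        height_B_mm=height_above_dorsum(vessels.B[side], frame),
        width_B_mm=width_from_midline(vessels.B[side], frame),
        cz_mm=_arch_reference_distance(traj.C, arch, cz_mode),
        cl_mm=float(np.linalg.norm(traj.C - canthus)),
        c_vertical_mm=vertical,
        c_occipitofrontal_mm=occipitofrontal,
    )
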