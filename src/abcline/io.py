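"""File formats: meshes, landmark/vessel JSON, cohort CSV, NIfTI volumes.

Everything is written in millimetres in the dorsum-sellae frame; JSON
documents carry explicit ``units`` and ``frame`` fields so files remain
self-describing when moved between tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .craniometry import COHORT_COLUMNS, MeasurementRecord
from .errors import ParameterError, SchemaError
from .phantom import LandmarkSet, VascularPoints
from .trajectory import TrajectoryResult

FRAME_DESCRIPTION = "origin=dorsum sellae apex; +x right-lateral, +y anterior, +z superior"

MESH_FORMATS = {".ply", ".stl", ".obj"}


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in MESH_FORMATS:
        raise ParameterError(f"unsupported mesh format {path.suffix!r}; use PLY/STL/OBJ")
    mesh.export(path)
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() not in MESH_FORMATS:
        raise ParameterError(f"unsupported mesh format {path.suffix!r}; use PLY/STL/OBJ")
    loaded = trimesh.load(path, force="mesh", process=False)
    return loaded


def _vec(x) -> list[float]:
    return [float(v) for v in np.asarray(x)]


def write_landmarks_json(
    landmarks: LandmarkSet, vessels: VascularPoints | None, path: str | Path
) -> Path:
    doc = {
        "units": "mm",
        "frame": FRAME_DESCRIPTION,
        "landmarks": {
            "dorsum_sellae": _vec(landmarks.dorsum_sellae),
            "midsagittal_normal": _vec(landmarks.midsagittal_normal),
            "eac": {s: _vec(p) for s, p in landmarks.eac.items()},
            "lateral_canthus": {s: _vec(p) for s, p in landmarks.lateral_canthus.items()},
            "zygomatic_arch": {
                s: [_vec(p) for p in poly] for s, poly in landmarks.zygomatic_arch.items()
            },
        },
    }
    if vessels is not None:
        doc["vessels"] = {
            "A": _vec(vessels.A),
            "B": {s: _vec(p) for s, p in vessels.B.items()},
        }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def read_landmarks_json(path: str | Path) -> tuple[LandmarkSet, VascularPoints | None]:
    doc = json.loads(Path(path).read_text())
    try:
        lm = doc["landmarks"]
        landmarks = LandmarkSet(
            dorsum_sellae=np.array(lm["dorsum_sellae"], dtype=float),
            eac={s: np.array(p, dtype=float) for s, p in lm["eac"].items()},
            lateral_canthus={
                s: np.array(p, dtype=float) for s, p in lm["lateral_canthus"].items()
            },
            zygomatic_arch={
                s: np.array(poly, dtype=float) for s, poly in lm["zygomatic_arch"].items()
            },
            midsagittal_normal=np.array(
                lm.get("midsagittal_normal", [1.0, 0.0, 0.0]), dtype=float
            ),
        )
    except KeyError as exc:
        raise SchemaError(f"landmark file missing field: {exc.args[0]!r}") from exc
    vessels = None
    if "vessels" in doc:
        vs = doc["vessels"]
        vessels = VascularPoints(
            A=np.array(vs["A"], dtype=float),
            B={s: np.array(p, dtype=float) for s, p in vs["B"].items()},
        )
    return landmarks, vessels


def write_trajectories_jsonl(results: list[tuple[dict, TrajectoryResult]], path: str | Path) -> Path:
    """One JSON line per subject-side: metadata dict + trajectory fields."""
    path = Path(path)
    with path.open("w") as fh:
        for meta, tr in results:
            rec = dict(meta)
            rec.update(
                {
                    "units": "mm",
                    "A": _vec(tr.A),
                    "B": _vec(tr.B),
                    "C": _vec(tr.C),
                    "t_B": tr.t_B,
                    "t_C": tr.t_C,
                    "face_index": tr.face_index,
                    "collinearity_residual": tr.collinearity_residual,
                }
            )
            fh.write(json.dumps(rec) + "\n")
    return path


def write_cohort_csv(records: list[MeasurementRecord] | pd.DataFrame, path: str | Path) -> Path:
    if isinstance(records, pd.DataFrame):
        df = records[COHORT_COLUMNS]
    else:
        df = pd.DataFrame([r.as_dict() for r in records], columns=COHORT_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so write -> read is lossless to the last ulp
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing columns: {missing}")
    return df


def write_nifti(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a binary volume as NIfTI-1 (uint8)."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume).astype(np.uint8), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return Path(path)


def parse_length_mm(text: str | float) -> float:
    """Parse a length with explicit unit suffix ('30mm', '3cm') to mm.

    Bare numbers are taken as mm, the package-wide internal unit.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip().lower()
    if s.endswith("cm"):
        return float(s[:-2]) * 10.0
    if s.endswith("mm"):
        return float(s[:-2])
    return float(s)
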