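"""End-to-end pipeline: generate -> trajectory -> measure -> classify -> correlate.

Every stage is a pure function of the :class:`~abcline.config.RunConfig`
and its seed; the run manifest records the full config, seed, library
versions and a SHA-256 per numeric output so a re-run can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig
from .craniometry import measure_all
from .errors import AbclineError
from .phantom import generate_skull, sample_vascular_points, voxelize_and_extract
from .stats import classify_oza, pearson_with_bonferroni, summarize
from .trajectory import compute_point_C

log = logging.getLogger("abcline")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_cohort_table(config: RunConfig) -> pd.DataFrame:
    """Run the geometric stages and return the cohort measurement table."""
    anatomy = generate_skull(config.skull_params(), seed=config.seed)
    samples = sample_vascular_points(anatomy, config.cohort_params(), seed=config.seed)
    records = []
    for sample in samples:
        side = sample.side
        traj = compute_point_C(
            sample.A, sample.B[side], anatomy.mesh, validate_inside=False
        )
        records.append(
            measure_all(
                anatomy,
                traj,
                side,
                vessels=sample,
                subject_id=sample.subject_id,
                cz_mode=config.cz_mode,
            )
        )
    return pd.DataFrame([r.as_dict() for r in records])


def classify_table(cohort: pd.DataFrame, low_mm: float, high_mm: float) -> pd.DataFrame:
    out = cohort.copy()
    out["decision"] = [
        classify_oza(cz, cl, low_mm, high_mm).label.value
        for cz, cl in zip(out["cz_mm"], out["cl_mm"])
    ]
    return out


def _scatter_plot(cohort: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        cohort["c_occipitofrontal_mm"], cohort["c_vertical_mm"], s=12, alpha=0.7
    )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("point C anterior of EAC (mm)")
    ax.set_ylabel("point C above EAC (mm)")
    ax.set_title("Distribution of the cranial exit point C")
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": None} if path.suffix == ".png" else None)
    plt.close(fig)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and write the artifact bundle.

    Returns a manifest dict (also written as ``manifest.json``) mapping
    each output to its path and, for numeric outputs, its SHA-256.
    """
    out = Path(out_dir or config.output.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    hashes: dict[str, str] = {}
    paths: dict[str, str] = {}

    def stage(name):
        log.info("stage %s starting (seed=%d)", name, config.seed)
        return time.perf_counter()

    try:
        t0 = stage("generate")
        anatomy = generate_skull(config.skull_params(), seed=config.seed)
        timings["generate"] = time.perf_counter() - t0

        if config.output.write_mesh:
            mesh_path = out / f"skull.{config.output.mesh_format}"
            io.write_mesh(anatomy.mesh, mesh_path)
            paths["mesh"] = str(mesh_path)
        lm_path = io.write_landmarks_json(
            anatomy.landmarks, anatomy.vessels, out / "landmarks.json"
        )
        paths["landmarks"] = str(lm_path)
        hashes["landmarks.json"] = _sha256(lm_path)

        if config.output.write_volume:
            t0 = stage("voxelize")
            vox = voxelize_and_extract(anatomy, config.output.volume_voxel_mm)
            io.write_nifti(vox.shell, vox.affine, out / "skull_shell.nii")
            paths["volume"] = str(out / "skull_shell.nii")
            timings["voxelize"] = time.perf_counter() - t0

        t0 = stage("trajectory+measure")
        samples = sample_vascular_points(anatomy, config.cohort_params(), seed=config.seed)
        records = []
        traj_rows = []
        for sample in samples:
            traj = compute_point_C(
                sample.A, sample.B[sample.side], anatomy.mesh, validate_inside=False
            )
            traj_rows.append(
                ({"subject_id": sample.subject_id, "side": sample.side}, traj)
            )
            records.append(
                measure_all(
                    anatomy,
                    traj,
                    sample.side,
                    vessels=sample,
                    subject_id=sample.subject_id,
                    cz_mode=config.cz_mode,
                )
            )
        cohort = pd.DataFrame([r.as_dict() for r in records])
        timings["trajectory+measure"] = time.perf_counter() - t0

        cohort_path = io.write_cohort_csv(cohort, out / "cohort.csv")
        hashes["cohort.csv"] = _sha256(cohort_path)
        paths["cohort"] = str(cohort_path)
        traj_path = io.write_trajectories_jsonl(traj_rows, out / "trajectories.jsonl")
        hashes["trajectories.jsonl"] = _sha256(traj_path)
        paths["trajectories"] = str(traj_path)

        t0 = stage("classify")
        decisions = classify_table(
            cohort, config.thresholds.low_mm, config.thresholds.high_mm
        )
        dec_path = out / "decisions.csv"
        decisions.to_csv(dec_path, index=False)
        hashes["decisions.csv"] = _sha256(dec_path)
        paths["decisions"] = str(dec_path)
        timings["classify"] = time.perf_counter() - t0

        t0 = stage("correlate")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report = pearson_with_bonferroni(
                cohort,
                family_alpha=config.statistics.family_alpha,
                m=config.statistics.m,
            )
        for w in caught:
            log.warning("correlate: %s", w.message)
        corr_path = out / "correlations.csv"
        report.to_frame().to_csv(corr_path, index=False)
        hashes["correlations.csv"] = _sha256(corr_path)
        paths["correlations"] = str(corr_path)
        (out / "correlations.txt").write_text(report.to_text() + "\n")
        paths["correlations_text"] = str(out / "correlations.txt")

        summary = summarize(cohort)
        sum_path = out / "summary.csv"
        summary.table.to_csv(sum_path)
        hashes["summary.csv"] = _sha256(sum_path)
        paths["summary"] = str(sum_path)
        timings["correlate"] = time.perf_counter() - t0

        t0 = stage("plot")
        scatter_path = out / f"scatter_point_C.{config.output.scatter_format}"
        _scatter_plot(cohort, scatter_path)
        paths["scatter"] = str(scatter_path)
        timings["plot"] = time.perf_counter() - t0
    except AbclineError as exc:
        raise AbclineError(f"pipeline failed: {exc}") from exc

    manifest = {
        "package": "abcline",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "versions": _library_versions(),
        "outputs": paths,
        "sha256": hashes,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _library_versions() -> dict[str, str]:
    import pandas
    import scipy
    import trimesh

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "trimesh": trimesh.__version__,
    }
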