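"""Packaged reference data.

The five-patient surgical series ships as a plain CSV under
``abcline/data`` with its transcription documented in the file header;
the loader verifies a checksum so silent corruption of the packaged
values surfaces as a :class:`~abcline.errors.PackagingError`.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import PackagingError

TABLE2_SHA256 = "f8c1e6f3a51bd8976ed41bb196ab37409375a296648919f6d2ccf109d3d4c6df"

_REQUIRED_COLUMNS = [
    "patient",
    "age",
    "sex",
    "location",
    "size_mm",
    "ruptured",
    "height_A_mm",
    "height_B_mm",
    "width_B_mm",
    "cz_mm",
    "cl_mm",
    "approach",
]


def load_table2_fixture(path: str | Path | None = None, *, verify: bool = True) -> pd.DataFrame:
    """Load the five-patient reference table.

    Parameters
    ----------
    path
        Override the packaged file (mainly for testing); checksum
        verification only applies to the packaged copy.
    """
    if path is None:
        ref = resources.files("abcline").joinpath("data/table2.csv")
        raw = ref.read_bytes()
        if verify and hashlib.sha256(raw).hexdigest() != TABLE2_SHA256:
            raise PackagingError("packaged table2.csv failed its checksum")
        import io

        df = pd.read_csv(io.BytesIO(raw), comment="#")
    else:
        raw = Path(path).read_bytes()
        if verify and hashlib.sha256(raw).hexdigest() != TABLE2_SHA256:
            raise PackagingError(f"{path} does not match the packaged table2 checksum")
        df = pd.read_csv(path, comment="#")

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PackagingError(f"table2 fixture missing columns: {missing}")
    if len(df) != 5:
        raise PackagingError(f"table2 fixture must have exactly 5 records, got {len(df)}")
    if not df["height_A_mm"].between(3, 12).all():
        raise PackagingError("table2 heights of A must lie within [3, 12] mm")
    if (df[["cz_mm", "cl_mm"]] < 0).any().any():
        raise PackagingError("table2 distances must be non-negative")
    return df
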