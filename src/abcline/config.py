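"""Run configuration: schema-validated nested sections.

Unknown keys are rejected (``extra='forbid'``) so typos in a config file
fail loudly before any stage runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .phantom import (
    DEFAULT_HEIGHT_A,
    DEFAULT_HEIGHT_B,
    DEFAULT_WIDTH_B,
    CohortParams,
    SkullParams,
)

Quad = tuple[float, float, float, float]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SkullSection(_Section):
    semi_axes: tuple[float, float, float] = (70.0, 90.0, 65.0)
    center: tuple[float, float, float] = (0.0, 0.0, 35.0)
    subdivisions: int = 5


class PlacementSection(_Section):
    a_posterior_offset: float = -8.0
    b_anterior_offset: float = 10.0
    jitter_sd: float = 2.0
    a_lateral_sd: float = 0.7
    a_lateral_max: float = 2.0


class CohortSection(_Section):
    n: int = 80
    height_A: Quad = DEFAULT_HEIGHT_A
    height_B: Quad = DEFAULT_HEIGHT_B
    width_B: Quad = DEFAULT_WIDTH_B
    mirror_sides: bool = False


class ThresholdSection(_Section):
    low_mm: float = 30.0
    high_mm: float = 40.0


class StatisticsSection(_Section):
    family_alpha: float = 0.05
    m: int = 3


class OutputSection(_Section):
    out_dir: str = "results"
    mesh_format: str = "ply"
    scatter_format: str = "png"
    write_mesh: bool = True
    write_volume: bool = False
    volume_voxel_mm: float = 1.0


class RunConfig(_Section):
    skull: SkullSection = Field(default_factory=SkullSection)
    placement: PlacementSection = Field(default_factory=PlacementSection)
    cohort: CohortSection = Field(default_factory=CohortSection)
    thresholds: ThresholdSection = Field(default_factory=ThresholdSection)
    statistics: StatisticsSection = Field(default_factory=StatisticsSection)
    output: OutputSection = Field(default_factory=OutputSection)
    seed: int = 0
    cz_mode: str = "polyline"

    def skull_params(self) -> SkullParams:
        return SkullParams(
            semi_axes=self.skull.semi_axes,
            center=self.skull.center,
            subdivisions=self.skull.subdivisions,
        )

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            n=self.cohort.n,
            height_A=self.cohort.height_A,
            height_B=self.cohort.height_B,
            width_B=self.cohort.width_B,
            a_posterior_offset=self.placement.a_posterior_offset,
            b_anterior_offset=self.placement.b_anterior_offset,
            jitter_sd=self.placement.jitter_sd,
            a_lateral_sd=self.placement.a_lateral_sd,
            a_lateral_max=self.placement.a_lateral_max,
            mirror_sides=self.cohort.mirror_sides,
            seed=self.seed,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)
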