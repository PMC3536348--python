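"""Schema-validated run configuration (YAML/JSON) for the pipeline and CLI.

Every parameter is typed and range-checked by pydantic before any computation
starts, and unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .phantom import StudySpec
from .snake import SnakeParams
from .wall_segmentation import SegmentationParams


class SnakeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(0.1, ge=0)
    beta: float = Field(0.1, ge=0)
    gamma: float = Field(1.0, gt=0)
    kappa: float = Field(2.0, gt=0)
    n_points: int = Field(100, ge=8)
    max_iter: int = Field(400, ge=1)
    move_tol_mm: float = Field(1e-3, gt=0)
    resample_every: int = Field(10, ge=0)

    def to_params(self) -> SnakeParams:
        return SnakeParams(**self.model_dump())


class GvfConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mu: float = Field(0.05, gt=0)
    max_iter: int = Field(2000, ge=1)
    tol: float = Field(1e-4, gt=0)
    edge_blur_sigma_px: float = Field(1.0, ge=0)


class StudyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_animals: int = Field(6, ge=1)
    followup_animals: int = Field(3, ge=0)
    slices_per_region: int = Field(6, ge=1)
    spacing_mm: float = Field(0.1, gt=0)
    image_size_px: int = Field(192, ge=32)
    lumen_radius_mm: float = Field(1.5, gt=0)
    lesion_thickness_mm: tuple[float, float, float] = (0.3, 0.7, 0.55)
    proximal_thickness_mm: float = Field(0.3, ge=0)
    animal_sd_mm: float = Field(0.05, ge=0)
    slice_sd_mm: float = Field(0.03, ge=0)
    center_jitter_mm: float = Field(0.1, ge=0)
    noise_sd: float = Field(0.03, ge=0, lt=1)
    blur_sigma_mm: float = Field(0.12, ge=0)
    with_distractor: bool = True
    timepoints: tuple[str, ...] = ("baseline", "week4", "week10")

    def to_spec(self) -> StudySpec:
        return StudySpec(**self.model_dump())


class RunConfig(BaseModel):
    """Full configuration of an end-to-end phantom study run."""

    model_config = ConfigDict(extra="forbid")

    out_dir: Path = Path("vesselwall_run")
    rng_seed: int = Field(0, ge=0)
    study: StudyConfig = Field(default_factory=StudyConfig)
    snake: SnakeConfig = Field(default_factory=SnakeConfig)
    gvf: GvfConfig = Field(default_factory=GvfConfig)
    inflation_mm: float = Field(0.2, ge=0)
    mask_inner_margin_mm: float = Field(0.12, ge=0)
    init_radius_factor: float = Field(1.4, gt=1.0, description="initial circle radius as a multiple of the true lumen radius")
    write_images: bool = False
    log_level: str = "INFO"

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            snake=self.snake.to_params(),
            gvf_mu=self.gvf.mu,
            gvf_max_iter=self.gvf.max_iter,
            gvf_tol=self.gvf.tol,
            edge_blur_sigma_px=self.gvf.edge_blur_sigma_px,
            inflation_mm=self.inflation_mm,
            mask_inner_margin_mm=self.mask_inner_margin_mm,
        )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    import json

    import yaml

    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
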