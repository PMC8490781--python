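"""Declarative pipeline configuration with YAML loading and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .registration import RegistrationConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, validated at load time.

    Fields override the owning module's defaults; see the module
    docstrings for semantics and units.
    """

    working_size: int = 512
    pixel_spacing_mm: float = 1.0  # fallback for formats without geometry
    slice_thickness_mm: float = 5.0
    template_roi: tuple[int, int, int, int] | None = None
    search_radius: int = 15
    subpixel: bool = False
    alpha_min_deg: float = -10.0
    alpha_max_deg: float = 10.0
    alpha_step_deg: float = 0.5
    rmax_grid: tuple[float, ...] | None = None
    delta_t: float = 0.5
    t0: float | None = None
    min_area: int = 25
    change_threshold: float | None = None
    volume_convention: str = "classic"
    seed: int = 0
    output_dir: str = "tempsub_out"

    def __post_init__(self) -> None:
        if self.working_size < 64:
            raise ValueError("working_size must be >= 64")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be > 0")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.alpha_step_deg <= 0 or self.alpha_max_deg < self.alpha_min_deg:
            raise ValueError("invalid alpha grid")
        if self.volume_convention not in ("classic", "printed"):
            raise ValueError("volume_convention must be 'classic' or 'printed'")
        if self.change_threshold is not None and self.change_threshold <= 0:
            raise ValueError("change_threshold must be > 0 when set")

    @property
    def alpha_grid_deg(self) -> tuple[float, ...]:
        import numpy as np

        return tuple(
            np.arange(
                self.alpha_min_deg,
                self.alpha_max_deg + self.alpha_step_deg / 2,
                self.alpha_step_deg,
            )
        )

    def registration_config(self) -> RegistrationConfig:
        return RegistrationConfig(
            template_roi=self.template_roi,
            search_radius=self.search_radius,
            subpixel=self.subpixel,
            alpha_grid_deg=self.alpha_grid_deg,
            rmax_grid=self.rmax_grid,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("template_roi", "rmax_grid"):
            if isinstance(data.get(key), list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
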