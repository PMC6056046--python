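"""Structured-text (TOML) protocol configuration: schema and loading.

A config file describes which tissues to use, the acquisition geometry, the
SNR convention, and one of: a single sequence evaluation, a parameter sweep,
or a named optimization plan with optional in-vivo overrides.  Validation is
strict: unknown keys are rejected and all violations are reported together.
Packaged preset configs mirroring the study's experiments ship under
``mrseqopt/configs`` and are addressable by name.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import presets
from .acquisition import GEOMETRY_2D, AcquisitionGeometry, EspBwTable, SnrConfig
from .sweep import SweepSpec
from .tissues import catalog, read_catalog_csv

__all__ = [
    "ProtocolConfig",
    "ConfigError",
    "load_config",
    "loads_config",
    "preset_config_path",
    "packaged_configs",
]


class ConfigError(ValueError):
    """Invalid protocol configuration; the message lists all violations."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TissuesSection(_Strict):
    condition: Literal["pre", "post"] = "pre"
    csv: str | None = None  # optional user catalog replacing the built-in one


class GeometrySection(_Strict):
    fov_x_mm: float = GEOMETRY_2D.fov_x_mm
    fov_y_mm: float = GEOMETRY_2D.fov_y_mm
    dz_mm: float = GEOMETRY_2D.dz_mm
    n_fe: int = GEOMETRY_2D.n_fe
    n_pe: int = GEOMETRY_2D.n_pe
    n_slices_or_nz: int = GEOMETRY_2D.n_slices_or_nz
    mode: Literal["2D", "3D"] = "2D"
    bw: float = GEOMETRY_2D.bw

    def build(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(**self.model_dump())


class SnrSection(_Strict):
    exponent_p: float = Field(default=1.0, gt=0.0, le=1.0)

    def build(self) -> SnrConfig:
        return SnrConfig(self.exponent_p)


class SequenceSection(_Strict):
    """Flat parameter block for a single-sequence evaluation."""

    type: Literal["fse", "flair", "gre", "mprage"]
    tr_ms: float | None = None
    esp_ms: float | None = None
    etl: int | None = None
    te_eff_ms: float | None = None
    ti_ms: float | None = None
    te_ms: float | None = None
    fa_deg: float | None = None
    n_readouts: int | None = None
    td_ms: float | None = None
    readout_index: int | None = None
    nsa: int = 1

    def params(self) -> dict:
        out = self.model_dump(exclude={"type"}, exclude_none=True)
        return out


class SweepSection(_Strict):
    sequence: Literal["fse", "flair", "gre", "mprage"]
    varying: str
    grid: list[float] = Field(min_length=1)
    objective: list[str] | str
    fixed: dict[str, float] = Field(default_factory=dict)
    esp_bw: list[list[float]] | None = None  # [[esp, bw], ...]
    etl_schedule: dict[str, int] | None = None  # TOML keys are strings
    nsa_budget_s: float | None = None

    @model_validator(mode="after")
    def _check_objective(self) -> "SweepSection":
        if isinstance(self.objective, list) and len(self.objective) != 2:
            raise ValueError("objective must be a tissue name or a pair of names")
        return self

    def build(self) -> SweepSpec:
        objective = (
            tuple(self.objective) if isinstance(self.objective, list)
            else self.objective
        )
        esp_bw = (
            EspBwTable(tuple((e, b) for e, b in self.esp_bw))
            if self.esp_bw is not None else None
        )
        schedule = (
            {float(k): v for k, v in self.etl_schedule.items()}
            if self.etl_schedule is not None else None
        )
        return SweepSpec(
            sequence=self.sequence, varying=self.varying, grid=tuple(self.grid),
            objective=objective, fixed=self.fixed, esp_bw=esp_bw,
            etl_schedule=schedule, nsa_budget_s=self.nsa_budget_s,
        )


class PlanSection(_Strict):
    preset: str
    overrides: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_preset(self) -> "PlanSection":
        if self.preset not in presets.PLAN_NAMES:
            raise ValueError(
                f"unknown plan preset {self.preset!r}; available: {presets.PLAN_NAMES}"
            )
        return self


class PhantomSection(_Strict):
    noise_sd: float = Field(default=0.0, ge=0.0)
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    n_slices: int = Field(default=3, ge=1)


class ProtocolConfig(_Strict):
    """Validated top-level protocol configuration."""

    tissues: TissuesSection = TissuesSection()
    geometry: GeometrySection = GeometrySection()
    snr: SnrSection = SnrSection()
    sequence: SequenceSection | None = None
    sweep: SweepSection | None = None
    plan: PlanSection | None = None
    phantom: PhantomSection = PhantomSection()

    def tissue_map(self, base: Path | None = None) -> dict:
        """Tissue name → record for the configured condition."""
        if self.tissues.csv is not None:
            path = Path(self.tissues.csv)
            if base is not None and not path.is_absolute():
                path = base / path
            records = read_catalog_csv(path)
            return {
                t.name: t for t in records
                if t.condition == self.tissues.condition
            }
        return catalog(self.tissues.condition)


def loads_config(text: str) -> ProtocolConfig:
    """Parse and validate a TOML string."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"TOML parse error: {exc}") from exc
    try:
        return ProtocolConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            "invalid protocol config:\n" + "\n".join(lines)
        ) from exc


def load_config(path: str | Path) -> ProtocolConfig:
    """Load and validate a TOML protocol configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return loads_config(path.read_text())


def packaged_configs() -> list[str]:
    """Names of the preset configs shipped with the package."""
    root = resources.files("mrseqopt") / "configs"
    return sorted(p.name.removesuffix(".toml") for p in root.iterdir()
                  if p.name.endswith(".toml"))


def preset_config_path(name: str) -> Path:
    """Filesystem path of a packaged preset config (e.g. ``flair_pre``)."""
    root = resources.files("mrseqopt") / "configs"
    candidate = root / f"{name}.toml"
    if not candidate.is_file():
        raise KeyError(f"unknown preset config {name!r}; available: {packaged_configs()}")
    return Path(str(candidate))
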