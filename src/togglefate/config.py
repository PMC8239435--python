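"""Structured run configuration with strict validation.

One YAML file configures every pipeline stage; unknown keys are rejected
and all validation failures are reported together (pydantic).  The CLI
layers flag overrides on top and derives all randomness from the single
top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .model import ToggleParams
from .synth import DEFAULT_PROPORTIONS, SynthConfig

__all__ = [
    "ToggleParamsConfig",
    "ScalingConfig",
    "PoolsConfig",
    "SynthBlock",
    "RunConfig",
    "load_config",
    "write_manifest",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ToggleParamsConfig(_Strict):
    a: float = Field(1.0, gt=0)
    b: float = Field(1.0, gt=0)
    k: float = Field(1.0, gt=0)
    n: int = Field(4, ge=1)
    theta: float = Field(0.5, gt=0)
    x_max: float = Field(2.2, gt=0)
    t_max: float = Field(100.0, gt=0)
    conv_tol: float = Field(1e-6, gt=0)
    attract_eps: float = Field(0.05, gt=0)

    def to_params(self) -> ToggleParams:
        return ToggleParams(**self.model_dump())


class ScalingConfig(_Strict):
    pooled: bool = True


class PoolsConfig(_Strict):
    immunogenic: list[str] = ["IRF1", "IRF4"]
    tolerogenic: list[str] = ["KRAS", "SOX4", "IRF4", "RELB", "ELK1"]

    @field_validator("immunogenic", "tolerogenic")
    @classmethod
    def _non_empty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("pool must be non-empty")
        return v


class SynthBlock(_Strict):
    n_cells_per_condition: int = Field(375, ge=1)
    fate_proportions: dict[str, list[float]] = Field(
        default_factory=lambda: {c: list(p) for c, p in DEFAULT_PROPORTIONS.items()}
    )
    tf_genes_x: list[str] = ["IRF1", "IRF4"]
    tf_genes_y: list[str] = ["KRAS", "SOX4", "IRF4", "RELB", "ELK1"]
    n_signature_genes: int = Field(20, ge=0)
    n_background_genes: int = Field(200, ge=0)
    base_mean: float = Field(0.5, gt=0)
    effect_size: float = Field(4.0, ge=1)
    dispersion: float = Field(2.0, gt=0)
    depth_variation: float = Field(0.3, ge=0)

    def to_synth_config(self, seed: int) -> SynthConfig:
        return SynthConfig(
            n_cells_per_condition=self.n_cells_per_condition,
            fate_proportions={c: tuple(p) for c, p in self.fate_proportions.items()},
            tf_genes_x=tuple(self.tf_genes_x),
            tf_genes_y=tuple(self.tf_genes_y),
            n_signature_genes=self.n_signature_genes,
            n_background_genes=self.n_background_genes,
            base_mean=self.base_mean,
            effect_size=self.effect_size,
            dispersion=self.dispersion,
            depth_variation=self.depth_variation,
            seed=seed,
        )


class PathsConfig(_Strict):
    matrix: Optional[str] = None
    metadata: Optional[str] = None
    x_axis_signature: Optional[str] = None
    y_axis_signature: Optional[str] = None
    out_dir: str = "results"

    def validate_exist(self) -> list[str]:
        problems = []
        for name in ("matrix", "metadata", "x_axis_signature", "y_axis_signature"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                problems.append(f"paths.{name}: no such file {value!r}")
        return problems


class RunConfig(_Strict):
    paths: PathsConfig = PathsConfig()
    params: ToggleParamsConfig = ToggleParamsConfig()
    scaling: ScalingConfig = ScalingConfig()
    pools: PoolsConfig = PoolsConfig()
    synth: SynthBlock = SynthBlock()
    log_level: str = "INFO"
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when omitted)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    config = RunConfig.model_validate(raw)  # raises with all failures listed
    problems = config.paths.validate_exist()
    if problems:
        raise FileNotFoundError("; ".join(problems))
    return config


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def write_manifest(out_dir: str | Path, config: RunConfig, inputs: dict[str, str | Path]) -> Path:
    """Write a run manifest: config echo, package version, input checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "togglefate",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": config.model_dump(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if p is not None and Path(p).is_file()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
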