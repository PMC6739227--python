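"""Run configuration: validated YAML-backed settings for the pipeline.

A single :class:`RunConfig` drives the CLI stages (simulate, fit, ppc,
gcomp).  Unknown keys are rejected so that typos fail loudly before any
stage runs; a manifest (config hash, seeds, package version, artifacts)
is written next to the outputs for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Strict):
    M: int = 12
    visit_times: list[float] | None = None


class ColumnsConfig(_Strict):
    id: str = "id"
    visit: str = "visit"
    y: str = "y"
    dropout: str = "dropout_visit"


class TermsConfig(_Strict):
    longitudinal: list[str]
    hazard: list[str]


class PriorsConfig(_Strict):
    beta_sd: float = 10.0
    delta_sd: float = 10.0
    alpha_gamma_sd: float = 2.0
    sigma_eps_shape: float = 0.001
    sigma_eps_rate: float = 0.001
    sigma_b_upper: float = 5.0


class MCMCSection(_Strict):
    chains: int = 3
    burn_in: int = 5000
    draws: int = 3000
    thin: int = 5


class SensitivitySection(_Strict):
    prior_low: float = -2.0
    prior_mode: float = -1.0
    prior_high: float = 0.0
    sigma_mode: str = "group"
    group_cols: list[str] = Field(default_factory=list)


class ProfileConfig(_Strict):
    label: str
    values: dict[str, float]


class GcompSection(_Strict):
    n_draws: int = 50
    n_mc: int = 10000
    summary_visits: list[int] = Field(default_factory=lambda: [6, 12])
    contrast_pairs: list[list[str]] = Field(default_factory=list)


class SimulateSection(_Strict):
    kind: str = "hers_like"  # or "two_arm"
    N: int = 200
    intermittent_rate: float = 0.0


class RunConfig(_Strict):
    """Top-level configuration for a pipeline run."""

    dataset: str | None = None
    outdir: str = "spmsens_output"
    seed: int = 0
    verbosity: int = 1
    design: DesignConfig = Field(default_factory=DesignConfig)
    columns: ColumnsConfig = Field(default_factory=ColumnsConfig)
    terms: TermsConfig | None = None
    priors: PriorsConfig = Field(default_factory=PriorsConfig)
    mcmc: MCMCSection = Field(default_factory=MCMCSection)
    sensitivity: SensitivitySection = Field(default_factory=SensitivitySection)
    profiles: list[ProfileConfig] = Field(default_factory=list)
    gcomp: GcompSection = Field(default_factory=GcompSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)

    @model_validator(mode="after")
    def _check(self):
        if self.design.M < 2:
            raise ValueError("design.M must be >= 2")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, separators=(",", ":"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, outdir: Path, artifacts: list[str]) -> Path:
    from . import __version__

    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": sorted(artifacts),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
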