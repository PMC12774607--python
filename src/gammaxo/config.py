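"""Pipeline configuration: a single YAML file, schema-validated before any
computation, every option overridable by a CLI flag. All randomness flows
from the single ``seed``."""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class McmcConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iter: int = 25_000
    burn_in: int = 5_000
    n_chains: int = 3
    target_rejection: float = 0.4
    swap_interval: int = 1


class PriorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_nu: float = 1.0
    sigma_p: float = 1.0
    intercept_sd: float = 10.0


class NumericConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    series_rel_tol: float = 1e-12
    series_max_terms: int = 500
    quad_rel_tol: float = 1e-8
    min_distance: float = 1e-6


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_meioses_per_sex: int = 474
    nu_female: float = 11.2
    p_female: float = 0.0094
    nu_male: float = 18.6
    p_male: float = 0.027
    n_sim: int = 20  # posterior predictive replicates


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    crossovers: Optional[str] = None
    segments: Optional[str] = None
    map: Optional[str] = None
    column_map: Optional[dict[str, str]] = None
    scheme: Literal["by_sex", "by_sex_and_size", "by_sex_and_chromosome"] = "by_sex"
    model: Literal["gamma", "sprinkling"] = "sprinkling"
    method: Literal["mcmc", "ml"] = "mcmc"
    include_x: bool = False
    seed: int = 0
    out_dir: str = "gammaxo_out"
    mcmc: McmcConfig = McmcConfig()
    prior: PriorConfig = PriorConfig()
    numeric: NumericConfig = NumericConfig()
    sim: SimConfig = SimConfig()

    @classmethod
    def load(cls, path: str | None, overrides: dict | None = None) -> "PipelineConfig":
        raw: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh)
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path} must contain a mapping")
            raw = loaded
        for key, val in (overrides or {}).items():
            if val is None:
                continue
            node = raw
            parts = key.split(".")
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = val
        try:
            cfg = cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc
        if cfg.mcmc.burn_in >= cfg.mcmc.n_iter:
            raise ConfigError(
                f"burn_in ({cfg.mcmc.burn_in}) must be smaller than n_iter "
                f"({cfg.mcmc.n_iter})"
            )
        return cfg

    def run_id(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]
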