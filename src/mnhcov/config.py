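"""Run configuration: a single YAML mapping, validated strictly.

Unknown keys are rejected (with a close-match suggestion), every default is
recorded, and all referenced input paths must exist at load time.
"""

from __future__ import annotations

import difflib
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    survey: Path
    boundaries: Optional[Path] = None
    adjacency: Optional[Path] = None
    outdir: Path = Path("out")


class PriorConfig(_Strict):
    sd_beta: float = Field(default=float(np.sqrt(1000.0)), gt=0)
    sigma_b_scale: float = Field(default=1.0, gt=0)


class McmcConfig(_Strict):
    chains: int = Field(default=4, ge=1)
    iters: int = Field(default=2500, ge=2)
    warmup: int = Field(default=1000, ge=0)
    thin: int = Field(default=1, ge=1)


class LinkageConfig(_Strict):
    urban_buffer_m: float = Field(default=2000.0, gt=0)
    rural_buffer_m: float = Field(default=5000.0, gt=0)
    drop_ambiguous: bool = False


class SplitConfig(_Strict):
    fraction: float = Field(default=0.25, gt=0, lt=1)
    unit: Literal["individual", "cluster"] = "individual"


class MetricsConfig(_Strict):
    pseudo_r2: Literal["r2", "pearson2"] = "r2"


class RunConfig(_Strict):
    paths: PathsConfig
    columns: dict[str, str] = Field(default_factory=dict)
    coding: Literal["ordinal", "categorical"] = "ordinal"
    outcomes: list[Literal["sba", "anc4", "pnc48"]] = Field(
        default_factory=lambda: ["sba", "anc4", "pnc48"]
    )
    priors: PriorConfig = Field(default_factory=PriorConfig)
    mcmc: McmcConfig = Field(default_factory=McmcConfig)
    linkage: LinkageConfig = Field(default_factory=LinkageConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    seed: int = 0
    region_column: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mcmc.warmup >= self.mcmc.iters:
            raise ValueError("mcmc.warmup must be smaller than mcmc.iters")
        if self.paths.boundaries is None and self.paths.adjacency is None:
            raise ValueError("either paths.boundaries or paths.adjacency is required")
        return self


_ALL_KEYS = sorted(
    set(RunConfig.model_fields)
    | set(PathsConfig.model_fields)
    | set(PriorConfig.model_fields)
    | set(McmcConfig.model_fields)
    | set(LinkageConfig.model_fields)
    | set(SplitConfig.model_fields)
    | set(MetricsConfig.model_fields)
)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending key; unknown keys get a
    "did you mean" suggestion.  Referenced input files must exist.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at top level")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            if err["type"] == "extra_forbidden":
                key = str(err["loc"][-1])
                close = difflib.get_close_matches(key, _ALL_KEYS, n=1)
                hint = f" (did you mean {close[0]!r}?)" if close else ""
                msgs.append(f"unknown key {loc!r}{hint}")
            else:
                msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError(f"{path}: " + "; ".join(msgs)) from exc
    for name in ("survey", "boundaries", "adjacency"):
        p = getattr(cfg.paths, name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{path}: paths.{name} does not exist: {p}")
    logger.info(
        "config loaded: coding=%s buffers=(%g, %g) split=%g seed=%d",
        cfg.coding,
        cfg.linkage.urban_buffer_m,
        cfg.linkage.rural_buffer_m,
        cfg.split.fraction,
        cfg.seed,
    )
    return cfg
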