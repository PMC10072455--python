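"""Dataset and configuration handling for the command-line workflows.

Site order is defined by the weights file; the dataset must match it row
for row (no implicit joins), which guards against the classic spatial-data
misalignment bug.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError

__all__ = ["read_dataset", "load_config", "RunConfig", "write_json"]

_COMMANDS = ("fit", "simulate", "risk", "bootstrap")


def read_dataset(csv_path, response: str, covariates: list[str] | None = None):
    """Read a site-level CSV into ``(y, X, covariate_names)``.

    Rows must be ordered like the spatial weights.  Missing columns,
    non-numeric cells and NA values raise :class:`DataError` with the
    offending location.
    """
    df = pd.read_csv(csv_path)
    if covariates is None:
        covariates = [c for c in df.columns if c != response]
    missing = [c for c in [response, *covariates] if c not in df.columns]
    if missing:
        raise DataError(f"missing column(s) {missing} in {csv_path}")
    sub = df[[response, *covariates]]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~sub.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(f"non-numeric cell at row {r}, column {sub.columns[c]!r}")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(f"NA value at row {r}, column {sub.columns[c]!r}")
    y = numeric[response].to_numpy(dtype=float)
    X = numeric[covariates].to_numpy(dtype=float)
    return y, X, list(covariates)


@dataclass
class RunConfig:
    """Validated configuration for one CLI run."""

    command: str
    data: str | None = None
    weights: str | None = None
    response: str | None = None
    main: list[str] = field(default_factory=list)
    nuisance: list[str] = field(default_factory=list)
    out: str | None = None
    seed: int = 0
    alpha: float = 0.05
    d_mode: str = "optimal"
    d: float | None = None
    ds: float | None = None
    verbosity: int = 1
    simulate: dict = field(default_factory=dict)
    risk: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.command not in _COMMANDS:
            raise ConfigError(f"command must be one of {_COMMANDS}, got {self.command!r}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected by name rather than silently ignored.
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {unknown}")
    if "command" not in raw:
        raise ConfigError("config must specify 'command'")
    return RunConfig(**raw)


def write_json(path, payload: dict, seed: int | None = None, config: dict | None = None) -> None:
    """Write an output artifact with reproducibility metadata embedded."""
    meta = {"carliu_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config"] = config
    out = {"metadata": meta, **payload}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(out, indent=2) + "\n")
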