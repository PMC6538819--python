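"""Synthetic study generation, configuration, and result serialization.

The raw-data route for simulating a two-group study lives here: two normal
subpopulations with unit standard deviation separated by the standardized
mean difference delta.  The engines reduce studies to the t statistic, but
the raw route is first-class (it backs the sequential engine's incremental
accumulation and the distributional-equivalence tests of the fixed-N fast
path).

Also here: the run manifest (enough provenance to reproduce any run
bit-for-bit), config round-tripping (YAML/JSON), and CSV/JSON writers with
fixed dialects (UTF-8, '.' decimal separator, RFC-4180 CSV via pandas).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fixed_n import DesignPrior, FixedNResult
from .priors import PriorSpec, get_prior
from .sequential import SequentialResult

__all__ = [
    "RawStudy",
    "generate_raw_study",
    "t_statistic",
    "RunManifest",
    "ConfigError",
    "read_config",
    "prior_from_config",
    "design_prior_from_config",
    "write_summary",
    "fixed_n_frame",
    "sequential_frame",
]


@dataclass(frozen=True)
class RawStudy:
    """A simulated two-group study with its generating parameters."""

    group1: np.ndarray
    group2: np.ndarray
    true_delta: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.group1) < 2 or len(self.group2) < 2:
            raise ValueError("both groups need at least 2 observations")

    @property
    def t(self) -> float:
        return t_statistic(self.group1, self.group2)


def generate_raw_study(delta: float, n_per_group: int, seed: int) -> RawStudy:
    """Two groups of ``n_per_group`` draws: Normal(delta, 1) vs Normal(0, 1)."""
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    rng = np.random.default_rng(seed)
    g1 = delta + rng.standard_normal(n_per_group)
    g2 = rng.standard_normal(n_per_group)
    return RawStudy(g1, g2, float(delta), int(seed))


def t_statistic(group1, group2) -> float:
    """Pooled-variance independent-samples t statistic (textbook formula)."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return float((x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2)))


# -- run manifest ----------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance of a run: version, config echo, seeds, timestamps."""

    config: dict
    master_seed: int
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )
    substreams: Optional[dict] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**d)


# -- configuration ---------------------------------------------------------


class ConfigError(ValueError):
    """Raised for malformed configuration files, naming the offending key."""


_PRIOR_KEYS = {"family", "location", "scale", "df", "lower", "upper", "preset"}
_TOP_KEYS = {"design_prior", "analysis_prior", "design", "planning", "output"}


def prior_from_config(cfg) -> PriorSpec:
    """Build an analysis prior from a config entry.

    Accepts a preset name (``"default"`` / ``"informed"``) or a mapping with
    ``{family, location, scale, df, lower, upper}``.
    """
    if isinstance(cfg, str):
        return get_prior(cfg)
    if not isinstance(cfg, dict):
        raise ConfigError(f"prior entry must be a name or mapping, got {cfg!r}")
    unknown = set(cfg) - _PRIOR_KEYS
    if unknown:
        raise ConfigError(f"unknown prior key(s): {sorted(unknown)}")
    if "preset" in cfg:
        return get_prior(cfg["preset"])
    if "family" not in cfg:
        raise ConfigError("prior mapping missing required key 'family'")
    kwargs = {k: cfg[k] for k in cfg}
    kwargs.setdefault("lower", -math.inf)
    kwargs.setdefault("upper", math.inf)
    return PriorSpec(**kwargs)


def design_prior_from_config(cfg) -> DesignPrior:
    """Build a design prior: ``{delta: x}`` or a distribution entry."""
    if isinstance(cfg, dict) and "delta" in cfg:
        extra = set(cfg) - {"delta"}
        if extra:
            raise ConfigError(f"unknown design prior key(s): {sorted(extra)}")
        return DesignPrior.point(cfg["delta"])
    return DesignPrior.from_prior(prior_from_config(cfg))


def read_config(path) -> dict:
    """Read and validate a YAML/JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "design" in cfg:
        kind = cfg["design"].get("kind")
        if kind not in ("fixed_n", "sequential"):
            raise ConfigError(
                f"design.kind must be 'fixed_n' or 'sequential', got {kind!r}"
            )
    return cfg


def write_summary(path, summary: dict, manifest: RunManifest) -> None:
    """Write a JSON summary carrying the run manifest."""
    payload = {"summary": _jsonable(summary), "manifest": manifest.to_dict()}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# -- result frames ---------------------------------------------------------


def fixed_n_frame(result: FixedNResult) -> pd.DataFrame:
    """One row per replication: (replicate, delta_drawn, t, log_bf10)."""
    return pd.DataFrame(
        {
            "replicate": np.arange(result.config.m),
            "delta_drawn": result.deltas,
            "t": result.ts,
            "log_bf10": result.log_bfs,
        }
    )


def sequential_frame(result: SequentialResult) -> pd.DataFrame:
    """One row per trajectory: (replicate, delta_drawn, final_n, side)."""
    return pd.DataFrame(
        {
            "replicate": np.arange(result.final_n.size),
            "delta_drawn": result.deltas,
            "final_n": result.final_n,
            "side": result.side.astype(str) if result.final_n.size else [],
        }
    )
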