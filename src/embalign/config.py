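"""Run configuration for the alignment pipeline.

All angular quantities are in degrees, all coordinates in micrometers
unless a cloud has been normalized (centered, scaled by its median
pairwise distance), in which case lengths are dimensionless.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class RunConfig:
    """Tunable parameters of atlas fitting, registration and diagnostics.

    Defaults follow the published method where it states a value
    (valley separation >= 30 degrees, random forest with 200 trees of
    depth 10) and this package's own choices elsewhere.
    """

    # coarse rotational search
    sweep_step_deg: float = 10.0
    k_seeds: int = 3
    min_valley_separation_deg: float = 30.0

    # entropic optimal transport
    sinkhorn_epsilon: float = 0.05
    sinkhorn_epsilon_min: float = 1e-3
    sinkhorn_anneal: float = 0.7
    sinkhorn_max_iters: int = 200
    sinkhorn_tol: float = 1e-6

    # soft-ICP refinement
    refine_max_iters: int = 60
    refine_tol: float = 1e-9

    # diagnostic random forest
    rf_n_estimators: int = 200
    rf_max_depth: int = 10
    rf_balanced: bool = False
    confidence_threshold: float = 0.5

    # atlas
    time_bin_width: float = 1.0
    covariance_jitter: float = 1e-6
    gp_restarts: int = 3

    # label transfer
    plan_weighted_assignment: bool = False

    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "sweep_step_deg", "k_seeds", "min_valley_separation_deg",
            "sinkhorn_epsilon", "sinkhorn_epsilon_min", "sinkhorn_max_iters",
            "sinkhorn_tol", "refine_max_iters", "refine_tol",
            "rf_n_estimators", "rf_max_depth", "time_bin_width",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.covariance_jitter < 0:
            raise ConfigError("covariance_jitter must be non-negative")
        if not 0 < self.sinkhorn_anneal <= 1:
            raise ConfigError("sinkhorn_anneal must lie in (0, 1]")
        if 360.0 % self.sweep_step_deg:
            raise ConfigError("sweep_step_deg must divide 360")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
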