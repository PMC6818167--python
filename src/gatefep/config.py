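"""Run configuration: defaults, validation, YAML loading, logging setup."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

logger = logging.getLogger("gatefep")


@dataclass
class RunConfig:
    """Pipeline-wide settings.

    Defaults follow the study conditions: 310 K, umbrella bias
    1000 kJ/mol/nm² on a 13–19 Å grid with 0.25 Å spacing, energies
    reported in kcal/mol.
    """

    temperature: float = 310.0  # K
    energy_unit: str = "kcal/mol"
    bias_force_constant: float = 1000.0  # kJ/mol/nm², converted on use
    grid_min: float = 13.0  # Å
    grid_max: float = 19.0  # Å
    grid_spacing: float = 0.25  # Å
    lambda_protocol: str = "abfe_complex"
    seed: int | None = None
    wham_tol: float = 1e-7  # kcal/mol on window offsets
    wham_max_iter: int = 100_000
    wham_bins: int = 200
    mbar_tol: float = 1e-10
    mbar_max_iter: int = 10_000
    cv_group_a: tuple = (113, 117)  # TM3 residue range, inclusive
    cv_group_b: tuple = (235, 239)  # TM6 residue range, inclusive
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigurationError(f"temperature must be > 0 K, got {self.temperature}")
        if self.grid_spacing <= 0:
            raise ConfigurationError(f"grid spacing must be > 0, got {self.grid_spacing}")
        if self.grid_max <= self.grid_min:
            raise ConfigurationError("grid_max must exceed grid_min")
        if self.energy_unit not in ("kcal/mol", "kJ/mol"):
            raise ConfigurationError(f"unknown energy unit {self.energy_unit!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        if "temperature" not in kwargs:
            logger.info("temperature not set in config; defaulting to 310 K")
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        payload = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigurationError("a random seed is required for stochastic stages")
        return int(self.seed)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
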