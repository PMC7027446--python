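"""Pipeline configuration: a validated, hashable bundle of settings."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import ConfigurationError
from .gas_physics import (
    DEFAULT_SCHMIDT_SET,
    DEFAULT_SOLUBILITY_BASIS,
    SCHMIDT_COEFFICIENTS,
    N2O_SOLUBILITY_MODELS,
)
from .survey_processing import DEFAULT_X_ATM_PPB, REGION_LANDUSE, SEASON_RULES


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with defaults.

    ``temperature_policy`` is either ``"class_mean"`` (Schmidt
    conversion at each land-use class's mean record temperature) or a
    fixed temperature in C. ``delta_granularity`` pools the excess
    concentration per class (default) or per class x stream order.
    ``rounding`` controls reported figures: totals to ``sig_figs``
    significant figures, percentage shares to the nearest
    ``share_step``.
    """

    seed: int = 1
    x_atm_ppb: float = DEFAULT_X_ATM_PPB
    gwp: float = 298.0
    schmidt_set: str = DEFAULT_SCHMIDT_SET
    solubility_basis: str = DEFAULT_SOLUBILITY_BASIS
    temperature_policy: Union[str, float] = "class_mean"
    season_rule: str = "meteorological"
    delta_granularity: str = "class"
    region_landuse: dict = field(default_factory=lambda: dict(REGION_LANDUSE))
    calibration: str = "paper"
    survey_path: Optional[str] = None
    strata_path: Optional[str] = None
    mc_enabled: bool = False
    mc_iterations: int = 2000
    mc_repetitions: int = 50
    sig_figs: int = 3
    share_step: float = 10.0

    def __post_init__(self):
        if self.x_atm_ppb <= 0:
            raise ConfigurationError("x_atm_ppb must be > 0")
        if self.gwp <= 0:
            raise ConfigurationError("gwp must be > 0")
        if self.schmidt_set not in SCHMIDT_COEFFICIENTS:
            raise ConfigurationError(
                f"unknown schmidt_set {self.schmidt_set!r}; "
                f"expected one of {sorted(SCHMIDT_COEFFICIENTS)}"
            )
        if self.solubility_basis not in N2O_SOLUBILITY_MODELS:
            raise ConfigurationError(
                f"unknown solubility_basis {self.solubility_basis!r}"
            )
        if self.season_rule not in SEASON_RULES:
            raise ConfigurationError(
                f"unknown season_rule {self.season_rule!r}"
            )
        if self.delta_granularity not in ("class", "order"):
            raise ConfigurationError(
                "delta_granularity must be 'class' or 'order'"
            )
        if isinstance(self.temperature_policy, str):
            if self.temperature_policy != "class_mean":
                try:
                    self.temperature_policy = float(self.temperature_policy)
                except ValueError:
                    raise ConfigurationError(
                        "temperature_policy must be 'class_mean' or a "
                        "temperature in C"
                    ) from None
        bad_classes = set(self.region_landuse.values()) \
            - {"forest", "agricultural"}
        if bad_classes:
            raise ConfigurationError(
                f"region_landuse maps to unknown class(es) {sorted(bad_classes)}"
            )
        if self.mc_iterations < 1 or self.mc_repetitions < 1:
            raise ConfigurationError("MC counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load from YAML; unknown keys are rejected by name."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {unknown}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable sha256 of the configuration (for output provenance)."""
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def round_total(value: float, sig_figs: int = 3) -> float:
    """Round a reported total to the configured significant figures."""
    if value == 0:
        return 0.0
    from math import floor, log10
    ndigits = sig_figs - 1 - floor(log10(abs(value)))
    return round(value, ndigits)


def round_share(value: float, step: float = 10.0) -> float:
    """Round a percentage share to the nearest step (default 10)."""
    return step * round(value / step)
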