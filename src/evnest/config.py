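"""YAML run configuration with a strict schema.

A run config fully determines a scan: the model (catalogue name or variant
code), the objective, sampler settings, optional prior-range and
initial-copy overrides, and the regulator grid.  Unknown keys are rejected
at every level, defaults are materialized on load, and the materialized
config is echoed to the log so any estimate can be reproduced from the log
alone.  CLI flags override config keys.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .apoptosis import VARIANTS, _NAME_TO_CODE
from .objectives import OBJECTIVE_KINDS
from .sampler import DEFAULT_CLASS_RANGES, SamplerConfig
from .scan import ScanSpec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_SAMPLER_KEYS = {"n_live", "termination_tol", "seed", "max_evaluations", "proposal"}
_SCAN_KEYS = {"variants", "regulator", "values", "start", "stop", "step"}
_TOP_KEYS = {
    "model", "objective", "prior_overrides", "initial_overrides",
    "sampler", "scan", "output_dir", "seed", "t_end", "n_points",
}


@dataclass
class RunConfig:
    """A validated, fully-defaulted run configuration."""

    model: str = "full"
    objective: str = "parp_cleavage"
    prior_overrides: dict[str, list[float]] = field(default_factory=dict)
    initial_overrides: dict[str, float] = field(default_factory=dict)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    scan_variants: tuple[str, ...] = ()
    scan_regulator: str = "XIAP"
    scan_values: tuple[float, ...] = ()
    output_dir: str = "results"
    t_end: float = 20_000.0
    n_points: int = 201

    def class_ranges(self) -> dict[str, tuple[float, float]]:
        ranges = dict(DEFAULT_CLASS_RANGES)
        for cls, pair in self.prior_overrides.items():
            ranges[cls] = (float(pair[0]), float(pair[1]))
        return ranges

    def to_scan_spec(self) -> ScanSpec:
        variants = self.scan_variants or (_NAME_TO_CODE.get(self.model, self.model),)
        values = self.scan_values or (0.0,)
        return ScanSpec(
            variants=tuple(variants),
            regulator_name=self.scan_regulator,
            regulator_values=tuple(values),
            objective=self.objective,
            sampler=self.sampler,
            fixed_overrides=dict(self.initial_overrides),
            t_end=self.t_end,
            n_points=self.n_points,
        )

    def normalized(self) -> dict:
        """Plain-dict form with all defaults materialized (dump target)."""
        return {
            "model": self.model,
            "objective": self.objective,
            "prior_overrides": {k: list(v) for k, v in self.prior_overrides.items()},
            "initial_overrides": dict(self.initial_overrides),
            "sampler": {
                "n_live": self.sampler.n_live,
                "termination_tol": self.sampler.termination_tol,
                "seed": self.sampler.seed,
                "max_evaluations": self.sampler.max_evaluations,
                "proposal": self.sampler.proposal,
            },
            "scan": {
                "variants": list(self.scan_variants),
                "regulator": self.scan_regulator,
                "values": [float(v) for v in self.scan_values],
            },
            "output_dir": self.output_dir,
            "t_end": self.t_end,
            "n_points": self.n_points,
        }


def _reject_unknown(data: dict, allowed: set[str], where: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown {where} key(s): {sorted(unknown)}")


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "config")

    model = str(data.get("model", "full"))
    if model not in VARIANTS and model not in _NAME_TO_CODE:
        raise ConfigError(
            f"unknown model {model!r}; catalogue: {sorted(_NAME_TO_CODE)} "
            f"or codes {sorted(VARIANTS)}"
        )
    objective = str(data.get("objective", "parp_cleavage"))
    if objective not in OBJECTIVE_KINDS:
        raise ConfigError(f"unknown objective {objective!r}; valid: {OBJECTIVE_KINDS}")

    prior_overrides = data.get("prior_overrides", {}) or {}
    for cls, pair in prior_overrides.items():
        if cls not in DEFAULT_CLASS_RANGES:
            raise ConfigError(f"unknown rate class in prior_overrides: {cls!r}")
        if len(pair) != 2 or not float(pair[0]) < float(pair[1]):
            raise ConfigError(f"prior_overrides[{cls!r}] must be [low, high] with low < high")

    sampler_data = dict(data.get("sampler", {}) or {})
    _reject_unknown(sampler_data, _SAMPLER_KEYS, "sampler")
    if "seed" in data:
        sampler_data.setdefault("seed", int(data["seed"]))
    sampler = SamplerConfig(
        n_live=int(sampler_data.get("n_live", 16_000)),
        termination_tol=float(sampler_data.get("termination_tol", 1e-4)),
        seed=int(sampler_data.get("seed", 0)),
        max_evaluations=int(sampler_data.get("max_evaluations", 10_000_000)),
        proposal=str(sampler_data.get("proposal", "single_ellipsoid")),
    )

    scan_data = dict(data.get("scan", {}) or {})
    _reject_unknown(scan_data, _SCAN_KEYS, "scan")
    values: tuple[float, ...] = ()
    if "values" in scan_data:
        values = tuple(float(v) for v in scan_data["values"])
    elif {"start", "stop", "step"} <= set(scan_data):
        values = tuple(
            np.arange(float(scan_data["start"]),
                      float(scan_data["stop"]) + 0.5 * float(scan_data["step"]),
                      float(scan_data["step"])).tolist()
        )

    cfg = RunConfig(
        model=model,
        objective=objective,
        prior_overrides={k: [float(a), float(b)] for k, (a, b) in prior_overrides.items()},
        initial_overrides={str(k): float(v) for k, v in
                           (data.get("initial_overrides", {}) or {}).items()},
        sampler=sampler,
        scan_variants=tuple(str(v) for v in scan_data.get("variants", [])),
        scan_regulator=str(scan_data.get("regulator", "XIAP")),
        scan_values=values,
        output_dir=str(data.get("output_dir", "results")),
        t_end=float(data.get("t_end", 20_000.0)),
        n_points=int(data.get("n_points", 201)),
    )
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load, validate, and default-materialize a YAML run config."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = config_from_dict(data)
    logger.info("loaded config %s: %s", path, cfg.normalized())
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.normalized(), sort_keys=False),
                          encoding="utf-8")
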