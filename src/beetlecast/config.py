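"""Run configuration: YAML loading, validation, defaults, round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from beetlecast.learners import LEARNER_NAMES

SUPPORTED_R = (1, 3, 5, 7)
SUPPORTED_H = (1, 2, 3, 4, 5)


class ConfigError(ValueError):
    """The run configuration is malformed or out of supported ranges."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    seed: int = 0
    n_rows: int = 24
    n_cols: int = 24
    year_start: int = 2005
    year_end: int = 2018
    r_values: list[int] = field(default_factory=lambda: [1, 3, 5, 7])
    h_values: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    c_values: list[int] | None = None  # None: all ranked covariates
    learners: list[str] = field(default_factory=lambda: list(LEARNER_NAMES))
    learner_params: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    n_test_years: int = 2
    mrmr_criterion: str = "MID"
    output_dir: str = "results"

    def validate(self) -> "RunConfig":
        bad_r = [r for r in self.r_values if r not in SUPPORTED_R]
        if bad_r:
            raise ConfigError(
                f"unsupported prediction lengths {bad_r}; supported: {SUPPORTED_R}"
            )
        bad_h = [h for h in self.h_values if h not in SUPPORTED_H]
        if bad_h:
            raise ConfigError(
                f"unsupported history lengths {bad_h}; supported: {SUPPORTED_H}"
            )
        if self.c_values is not None:
            bad_c = [c for c in self.c_values if not 1 <= c <= 14]
            if bad_c:
                raise ConfigError(f"number-of-covariates {bad_c} outside 1..14")
        bad_l = [l for l in self.learners if l not in LEARNER_NAMES]
        if bad_l:
            raise ConfigError(f"unknown learners {bad_l}; known: {LEARNER_NAMES}")
        if self.year_end <= self.year_start:
            raise ConfigError("year_end must exceed year_start")
        n_years = self.year_end - self.year_start + 1  # simulated years
        needed = max(self.r_values) + max(self.h_values)
        if n_years < needed + 2:
            raise ConfigError(
                f"year span covers {n_years} years; need at least "
                f"r_max + h_max + 2 = {needed + 2} so all splits are constructible"
            )
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("grid dimensions must be positive")
        if self.mrmr_criterion not in ("MID", "MIQ"):
            raise ConfigError(f"unknown mRMR criterion {self.mrmr_criterion!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_validate_config(path) -> RunConfig:
    """Load a YAML config, reject unknown keys, fill defaults, validate."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    return RunConfig(**raw).validate()


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
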