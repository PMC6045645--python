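"""Pipeline configuration: a documented YAML key-value file.

Required keys (paths, relative to the config file's directory unless
absolute): counts_dir, design, features_dir, tss, expression, out_dir.
Optional keys and their defaults::

    group_control: wt       group_case: mut
    window_bp: 200          fdr_threshold: 0.01     min_delta: 0.1
    df_mode: full           max_gap_bp: 1000        min_cpgs: 3
    tss_max_dist: 1000      seed: 0

Unknown keys are errors; thresholds are range-checked at parse time and path
existence is checked at run start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

_REQUIRED_PATHS = ("counts_dir", "design", "features_dir", "tss", "expression")

_DEFAULTS = {
    "group_control": "wt",
    "group_case": "mut",
    "window_bp": 200,
    "fdr_threshold": 0.01,
    "min_delta": 0.1,
    "df_mode": "full",
    "max_gap_bp": 1000,
    "min_cpgs": 3,
    "tss_max_dist": 1000,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    counts_dir: Path
    design: Path
    features_dir: Path
    tss: Path
    expression: Path
    out_dir: Path
    group_control: str = "wt"
    group_case: str = "mut"
    window_bp: int = 200
    fdr_threshold: float = 0.01
    min_delta: float = 0.1
    df_mode: str = "full"
    max_gap_bp: int = 1000
    min_cpgs: int = 3
    tss_max_dist: int = 1000
    seed: int = 0

    def echo(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = str(v) if isinstance(v, Path) else v
        return d


def _check_ranges(cfg: PipelineConfig) -> None:
    if not (0 < cfg.fdr_threshold <= 1):
        raise ConfigError(f"fdr_threshold must be in (0, 1], got {cfg.fdr_threshold}")
    if not (0 <= cfg.min_delta <= 1):
        raise ConfigError(f"min_delta must be in [0, 1], got {cfg.min_delta}")
    if cfg.window_bp < 0:
        raise ConfigError(f"window_bp must be >= 0, got {cfg.window_bp}")
    if cfg.max_gap_bp < 0:
        raise ConfigError(f"max_gap_bp must be >= 0, got {cfg.max_gap_bp}")
    if cfg.min_cpgs < 1:
        raise ConfigError(f"min_cpgs must be >= 1, got {cfg.min_cpgs}")
    if cfg.tss_max_dist < 0:
        raise ConfigError(f"tss_max_dist must be >= 0, got {cfg.tss_max_dist}")
    if cfg.df_mode not in ("full", "shared"):
        raise ConfigError(f"df_mode must be 'full' or 'shared', got {cfg.df_mode!r}")
    if cfg.group_control == cfg.group_case:
        raise ConfigError("group_control and group_case must differ")


def validate_config(path: str | Path, out_dir: str | Path | None = None) -> PipelineConfig:
    """Parse, default and range-check a pipeline config file.

    ``out_dir`` overrides the file's out_dir (for the CLI --out flag).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not parseable as YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")

    known = set(_REQUIRED_PATHS) | {"out_dir"} | set(_DEFAULTS)
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(map(repr, unknown))}")
    missing = [k for k in _REQUIRED_PATHS if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing required key(s): {', '.join(missing)}")
    if out_dir is None and "out_dir" not in raw:
        raise ConfigError(f"{path}: missing required key(s): out_dir")

    base = path.parent

    def _resolve(p) -> Path:
        p = Path(str(p))
        return p if p.is_absolute() else base / p

    kwargs: dict = {k: _resolve(raw[k]) for k in _REQUIRED_PATHS}
    kwargs["out_dir"] = Path(out_dir) if out_dir is not None else _resolve(raw["out_dir"])
    for key, default in _DEFAULTS.items():
        value = raw.get(key, default)
        if not isinstance(value, type(default)) and isinstance(default, (int, float)):
            try:
                value = type(default)(value)
            except (TypeError, ValueError):
                raise ConfigError(f"{path}: key {key!r} has invalid value {value!r}")
        kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    _check_ranges(cfg)
    return cfg
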