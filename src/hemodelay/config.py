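"""Configuration parsing, validation and result serialization.

A run configuration is a small structured-text file (YAML or JSON; the
YAML loader parses both) naming a scenario preset, parameter overrides,
integration controls and output options.  Unknown keys are rejected
rather than ignored, so typos fail loudly before any computation runs.

Results are written as a CSV trajectory (``t,P,N,A`` header, full
shortest-round-trip precision so a re-read reproduces the stored grid
bit-for-bit) plus a JSON sidecar recording every resolved parameter,
the seed and the verdicts — enough to rerun the simulation identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .dde import Trajectory
from .equilibrium import SteadyStateReport
from .parameters import ModelParameters, ParameterError
from .scenarios import PRESET_NAMES, Scenario, make_scenario

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_results",
    "read_trajectory",
]

log = logging.getLogger("hemodelay")


class ConfigError(ValueError):
    """Malformed, unknown-key or invariant-violating configuration."""


_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_TOP_KEYS = {
    "scenario", "parameters", "t_end", "step", "stride", "seed",
    "deprivation_mode", "initial", "out", "sidecar", "verbosity",
}
_INITIAL_KEYS = {"P", "N", "A"}


@dataclass
class RunConfig:
    """A fully resolved, validated run configuration."""

    scenario: str = "baseline"
    parameters: dict[str, Any] = field(default_factory=dict)
    t_end: float = 400.0
    step: float = 0.01
    stride: int = 10
    seed: int | None = None
    deprivation_mode: str = "frozen"
    initial: dict[str, float] = field(
        default_factory=lambda: {"P": 1000.0, "N": 10000.0, "A": 0.0})
    out: str | None = None
    sidecar: str | None = None
    verbosity: str = "info"

    def to_scenario(self) -> Scenario:
        return make_scenario(
            self.scenario,
            overrides=self.parameters,
            P0=self.initial["P"], N0=self.initial["N"], A0=self.initial["A"],
            t_end=self.t_end, step=self.step, seed=self.seed,
            deprivation_mode=self.deprivation_mode,
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(
    path: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> RunConfig:
    """Load and validate a run configuration.

    ``overrides`` (e.g. from CLI flags) take precedence over the file;
    the file takes precedence over defaults.  Raises :class:`ConfigError`
    naming the offending key on any problem.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"configuration file not found: {p}")
        try:
            loaded = yaml.safe_load(p.read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse {p}: {e}") from e
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{p} must contain a mapping at top level")
        raw.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            if k in raw:
                log.info("override: %s=%r replaces configured %r", k, v, raw[k])
            raw[k] = v

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

    cfg = RunConfig()
    params = dict(raw.get("parameters") or {})
    bad = set(params) - _PARAM_KEYS
    if bad:
        raise ConfigError(f"unknown parameter key(s): {sorted(bad)}")
    initial = dict(cfg.initial)
    upd = dict(raw.get("initial") or {})
    bad = set(upd) - _INITIAL_KEYS
    if bad:
        raise ConfigError(f"unknown initial-condition key(s): {sorted(bad)}")
    initial.update({k: float(v) for k, v in upd.items()})

    cfg = RunConfig(
        scenario=raw.get("scenario", cfg.scenario),
        parameters=params,
        t_end=float(raw.get("t_end", cfg.t_end)),
        step=float(raw.get("step", cfg.step)),
        stride=int(raw.get("stride", cfg.stride)),
        seed=None if raw.get("seed") is None else int(raw["seed"]),
        deprivation_mode=raw.get("deprivation_mode", cfg.deprivation_mode),
        initial=initial,
        out=raw.get("out"),
        sidecar=raw.get("sidecar"),
        verbosity=raw.get("verbosity", cfg.verbosity),
    )
    if cfg.scenario not in PRESET_NAMES:
        raise ConfigError(
            f"unknown scenario {cfg.scenario!r}; expected one of {PRESET_NAMES}")
    if cfg.t_end <= 0:
        raise ConfigError("t_end must be positive")
    if cfg.step <= 0:
        raise ConfigError("step must be positive")
    if cfg.stride < 1:
        raise ConfigError("stride must be >= 1")
    if any(v < 0 for v in cfg.initial.values()):
        raise ConfigError("initial conditions must be non-negative")
    # validate parameter overrides eagerly, before any computation
    try:
        cfg.to_scenario()
    except (ParameterError, ValueError) as e:
        raise ConfigError(str(e)) from e
    log.info("resolved configuration: %s", cfg.to_dict())
    return cfg


def write_results(
    trajectory: Trajectory,
    paths: dict[str, str | Path],
    report: SteadyStateReport | None = None,
    stride: int = 1,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write CSV trajectory + JSON sidecar; return the manifest of files.

    ``paths`` maps "csv" and optionally "sidecar" to destinations.  The
    CSV uses shortest round-trip floats so a re-read reproduces the
    stored values exactly; the sidecar carries the resolved parameters,
    seed and any steady-state verdicts.
    """
    manifest: list[Path] = []
    csv_path = Path(paths["csv"])
    idx = range(0, len(trajectory.t), stride)
    last = len(trajectory.t) - 1
    with open(csv_path, "w") as fh:
        fh.write("t,P,N,A\n")
        written_last = False

        def row(i: int) -> str:
            return (f"{float(trajectory.t[i])!r},{float(trajectory.y[i, 0])!r},"
                    f"{float(trajectory.y[i, 1])!r},{float(trajectory.y[i, 2])!r}\n")

        for i in idx:
            fh.write(row(i))
            written_last = i == last
        if not written_last:
            fh.write(row(last))
    manifest.append(csv_path)
    log.info("wrote trajectory: %s (%d rows, stride %d)",
             csv_path, len(list(idx)), stride)

    sidecar_path = Path(paths.get("sidecar") or csv_path.with_suffix(".json"))
    sidecar: dict[str, Any] = {
        "metadata": _jsonable(trajectory.metadata),
        "stride": stride,
    }
    if config is not None:
        sidecar["config"] = _jsonable(config.to_dict())
    if report is not None:
        sidecar["steady_state"] = _jsonable(report.to_dict())
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
    manifest.append(sidecar_path)
    log.info("wrote sidecar: %s", sidecar_path)
    return manifest


def read_trajectory(csv_path: str | Path):
    """Read a written trajectory CSV back into a DataFrame (exact values)."""
    import pandas as pd

    return pd.read_csv(csv_path, float_precision="round_trip")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):          # numpy scalar
        return obj.item()
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    return repr(obj)
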