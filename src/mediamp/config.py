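"""Flat key-value run configuration.

One key per physical symbol, strict SI units, ``#`` comments.  Model
keys are bare (``d1``, ``k3``, ``D_S_2`` for the layer-2 substrate
diffusivity, ...); solver keys live under the ``solver.`` namespace
(``solver.dt``, ...).  Unknown keys are rejected; omitted keys fall
back to the reference defaults and every substitution is logged.

A packaged ``table1`` configuration reproduces the reference parameter
set bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np

from .model import ModelParameters, default_parameters, validate_parameters
from .solver import SolverOptions

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "packaged_config_path"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


_LAYER_KEYS = {
    f"{base}_{i}": (base, i - 1) for base in ("D_S", "D_Mox", "D_Mred", "D_O2") for i in (1, 2, 3, 4)
}
_MODEL_SCALAR_KEYS = {
    "d1", "d2", "d3", "d4", "k1", "k2", "k3",
    "e0", "s0", "m0", "o0", "A", "F",
}
_MODEL_INT_KEYS = {"n_e"}
_SOLVER_KEYS = {
    "solver.points_per_layer": int,
    "solver.dt": float,
    "solver.epsilon": float,
    "solver.t_max": float,
    "solver.picard_tol": float,
    "solver.picard_max_iter": int,
    "solver.current_floor_fraction": float,
}


@dataclass(frozen=True)
class RunConfig:
    """A validated model-parameter block plus a solver-option block."""

    params: ModelParameters
    solver: SolverOptions

    def __eq__(self, other):
        if not isinstance(other, RunConfig):
            return NotImplemented
        for f in fields(ModelParameters):
            a, b = getattr(self.params, f.name), getattr(other.params, f.name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return self.solver == other.solver


def packaged_config_path(name: str = "table1") -> Path:
    """Filesystem path of a packaged configuration (``table1``)."""
    ref = resources.files("mediamp").joinpath("data", f"{name}.cfg")
    path = Path(str(ref))
    if not path.is_file():
        raise ConfigError(f"no packaged configuration named {name!r}")
    return path


def _parse_lines(text: str, origin: str) -> dict[str, str]:
    raw: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{origin}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in stripped.split("=", 1))
        if key in raw:
            raise ConfigError(f"{origin}:{lineno}: duplicate key {key!r}")
        raw[key] = value
    return raw


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a flat key-value configuration file.

    Raises :class:`ConfigError` on unknown keys, type violations or
    values outside their physical invariants; logs every defaulted key
    at info level.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    raw = _parse_lines(text, str(path))

    model_kwargs: dict = {}
    layer_values: dict[str, np.ndarray] = {}
    solver_kwargs: dict = {}
    for key, value in raw.items():
        try:
            if key in _MODEL_SCALAR_KEYS:
                model_kwargs[key] = float(value)
            elif key in _MODEL_INT_KEYS:
                model_kwargs[key] = int(value)
            elif key in _LAYER_KEYS:
                base, idx = _LAYER_KEYS[key]
                arr = layer_values.setdefault(
                    base, np.asarray(getattr(default_parameters(), base), dtype=float).copy()
                )
                arr[idx] = float(value)
            elif key in _SOLVER_KEYS:
                solver_kwargs[key.split(".", 1)[1]] = _SOLVER_KEYS[key](value)
            else:
                raise ConfigError(f"unknown configuration key {key!r} in {path}")
        except ValueError as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"bad value for {key!r} in {path}: {value!r}") from exc
    model_kwargs.update(layer_values)

    defaults = default_parameters()
    for f in fields(ModelParameters):
        if f.name not in model_kwargs:
            logger.info("config %s: %s defaulted to %r", path.name, f.name, getattr(defaults, f.name))
    default_opts = SolverOptions()
    for f in fields(SolverOptions):
        if f.name != "snapshot_times" and f.name not in solver_kwargs:
            logger.info(
                "config %s: solver.%s defaulted to %r", path.name, f.name, getattr(default_opts, f.name)
            )
    try:
        params = validate_parameters(ModelParameters(**model_kwargs))
        opts = SolverOptions(**solver_kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc
    return RunConfig(params=params, solver=opts)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write every key explicitly so the file round-trips exactly."""
    p, o = cfg.params, cfg.solver
    lines = ["# mediamp run configuration (strict SI units)"]
    for name in ("d1", "d2", "d3", "d4"):
        lines.append(f"{name} = {float(getattr(p, name))!r}")
    for base in ("D_S", "D_Mox", "D_Mred", "D_O2"):
        for i in range(4):
            lines.append(f"{base}_{i + 1} = {float(getattr(p, base)[i])!r}")
    for name in ("k1", "k2", "k3", "e0", "s0", "m0", "o0", "A", "F"):
        lines.append(f"{name} = {float(getattr(p, name))!r}")
    lines.append(f"n_e = {p.n_e}")
    lines.append(f"solver.points_per_layer = {o.points_per_layer}")
    lines.append(f"solver.dt = {o.dt!r}")
    lines.append(f"solver.epsilon = {o.epsilon!r}")
    lines.append(f"solver.t_max = {o.t_max!r}")
    lines.append(f"solver.picard_tol = {o.picard_tol!r}")
    lines.append(f"solver.picard_max_iter = {o.picard_max_iter}")
    lines.append(f"solver.current_floor_fraction = {o.current_floor_fraction!r}")
    Path(path).write_text("\n".join(lines) + "\n")
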