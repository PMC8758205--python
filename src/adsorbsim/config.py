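"""TOML run configuration: load, validate, round-trip.

A config file is a flat table of SI-unit keys for one subcommand plus the
bookkeeping fields ``master_seed`` and ``replicates``.  Validation checks
types, positivity and unknown keys, and reports every problem at once.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "SCHEMAS"]


class ConfigError(ValueError):
    """Raised with a list of all validation problems in a config file."""


# (type, must_be_positive, default) per key; None default means required
_COMMON = {
    "master_seed": (int, False, 0),
    "replicates": (int, True, 1),
}

SCHEMAS: dict[str, dict] = {
    "predict": {
        **_COMMON,
        "A": (float, True, None),
        "c_b": (float, True, None),
        "D": (float, True, None),
        "dt": (float, True, None),
        "a": (float, True, None),
        "t": (float, True, None),
    },
    "pde": {
        **_COMMON,
        "L": (float, True, None),
        "nx": (int, True, 1024),
        "D": (float, True, None),
        "c_b": (float, True, None),
        "dt": (float, True, None),
        "t_end": (float, True, None),
        "bc_left": (str, False, "absorbing"),
        "bc_right": (str, False, "reflective"),
    },
    "walk1d-reflect": {
        **_COMMON,
        "n": (int, True, None),
        "L": (float, True, None),
        "D": (float, True, None),
        "dt_obs": (float, True, None),
        "n_sub": (int, True, 1),
        "plane_x": (float, True, None),
        "frames": (int, True, None),
    },
    "walk1d-absorb": {
        **_COMMON,
        "n": (int, True, None),
        "L": (float, True, None),
        "D": (float, True, None),
        "dt": (float, True, None),
        "frames": (int, True, None),
        "hist_bins": (int, False, 0),
        "hist_every": (int, False, 0),
    },
    "sam": {
        **_COMMON,
        "c_b": (float, True, None),
        "D": (float, True, None),
        "a": (float, True, None),
        "A": (float, True, None),
        "L": (float, True, None),
        "dt": (float, True, None),
        "t_end": (float, True, None),
    },
    "biosense": {
        **_COMMON,
        "side": (float, True, None),
        "radius": (float, True, 1e-8),
        "n_sites": (int, True, 150),
        "c_b": (float, True, None),
        "D": (float, True, None),
        "dt": (float, True, None),
        "t_end": (float, True, None),
    },
}


@dataclass
class RunConfig:
    """Validated parameters for one subcommand run."""

    subcommand: str
    params: dict = field(default_factory=dict)

    @property
    def master_seed(self) -> int:
        return self.params.get("master_seed", 0)

    @property
    def replicates(self) -> int:
        return self.params.get("replicates", 1)

    def __getitem__(self, key: str):
        return self.params[key]


def _validate(subcommand: str, raw: dict) -> dict:
    if subcommand not in SCHEMAS:
        raise ConfigError(f"unknown subcommand {subcommand!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[subcommand]
    problems: list[str] = []
    out: dict = {}
    for key in raw:
        if key not in schema:
            problems.append(f"unknown key {key!r}")
    for key, (typ, positive, default) in schema.items():
        if key in raw:
            v = raw[key]
            if typ is float and isinstance(v, int) and not isinstance(v, bool):
                v = float(v)
            if not isinstance(v, typ) or isinstance(v, bool):
                problems.append(f"{key!r} must be {typ.__name__}, got {v!r}")
                continue
            if positive and not v > 0:
                problems.append(f"{key!r} must be strictly positive, got {v!r}")
                continue
            out[key] = v
        elif default is None:
            problems.append(f"missing required key {key!r}")
        else:
            out[key] = default
    if problems:
        raise ConfigError(
            f"invalid [{subcommand}] config ({len(problems)} problem(s)):\n  "
            + "\n  ".join(problems)
        )
    return out


def load_config(path, subcommand: str | None = None) -> RunConfig:
    """Load and validate a TOML config.

    The file holds one table named after the subcommand, e.g.::

        [sam]
        c_b = 6.022e23
        D = 5e-10
        ...

    If ``subcommand`` is None the file must contain exactly one table.
    """
    path = Path(path)
    with path.open("rb") as fh:
        doc = tomllib.load(fh)
    tables = [k for k, v in doc.items() if isinstance(v, dict)]
    if subcommand is None:
        if len(tables) != 1:
            raise ConfigError(
                f"expected exactly one subcommand table, found {tables!r}"
            )
        subcommand = tables[0]
    if subcommand not in doc:
        raise ConfigError(f"config has no [{subcommand}] table (found {tables!r})")
    params = _validate(subcommand, doc[subcommand])
    return RunConfig(subcommand=subcommand, params=params)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to TOML; load_config(save_config(c)) == c."""
    lines = [f"[{cfg.subcommand}]"]
    for key in sorted(cfg.params):
        lines.append(f"{key} = {_toml_scalar(cfg.params[key])}")
    Path(path).write_text("\n".join(lines) + "\n")
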