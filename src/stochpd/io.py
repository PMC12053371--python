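"""Run configuration, cohort fixtures, and provenance-stamped CSV/JSON output.

Configs are flat key=value text files (one pair per line, ``#`` comments);
every CSV and JSON written carries the full configuration echo, the seed and
the package version so a stochastic run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParams, DoseSchedule, Cell

__all__ = ["RunConfig", "generate_cohort", "write_csv", "write_json"]

COMMANDS = ("analytic", "simulate", "multidose", "sample-extinction", "critical-mu")

# defaults follow the multiple-dose simulation values (mu=1, lambda=0.4,
# delta=2.5, alpha=2, T=3, T_d=1)
_DEFAULTS = dict(
    command="analytic",
    mu=1.0, lam=0.4, delta=2.5, alpha=2.0,
    k_death=0.25, k_div=0.5, death_rate_kind="step",
    sustained=False, T=3.0, T_d=1.0, n_cycles=None,
    n0=100, reps=100, seed=0, horizon=30.0, cap=10**6,
    grid_max=30.0, grid_points=200,
    out=None,
)

_TYPES = dict(
    command=str, mu=float, lam=float, delta=float, alpha=float,
    k_death=float, k_div=float, death_rate_kind=str,
    sustained=bool, T=float, T_d=float, n_cycles=int,
    n0=int, reps=int, seed=int, horizon=float, cap=int,
    grid_max=float, grid_points=int, out=str,
)


@dataclass
class RunConfig:
    """Flat configuration for one CLI run."""

    command: str = _DEFAULTS["command"]
    mu: float = _DEFAULTS["mu"]
    lam: float = _DEFAULTS["lam"]
    delta: float = _DEFAULTS["delta"]
    alpha: float = _DEFAULTS["alpha"]
    k_death: float = _DEFAULTS["k_death"]
    k_div: float = _DEFAULTS["k_div"]
    death_rate_kind: str = _DEFAULTS["death_rate_kind"]
    sustained: bool = _DEFAULTS["sustained"]
    T: float = _DEFAULTS["T"]
    T_d: float = _DEFAULTS["T_d"]
    n_cycles: int | None = None
    n0: int = _DEFAULTS["n0"]
    reps: int = _DEFAULTS["reps"]
    seed: int = _DEFAULTS["seed"]
    horizon: float = _DEFAULTS["horizon"]
    cap: int = _DEFAULTS["cap"]
    grid_max: float = _DEFAULTS["grid_max"]
    grid_points: int = _DEFAULTS["grid_points"]
    out: str | None = None

    def __post_init__(self):
        if self.command not in COMMANDS:
            raise ValueError(f"unknown command {self.command!r}; choose from {COMMANDS}")

    def params(self) -> ModelParams:
        return ModelParams(
            mu=self.mu, lam=self.lam, delta=self.delta, alpha=self.alpha,
            k_death=self.k_death, k_div=self.k_div,
            death_rate_kind=self.death_rate_kind,
        )

    def schedule(self) -> DoseSchedule:
        if self.sustained:
            return DoseSchedule.sustained_dose()
        return DoseSchedule.cycles(self.T, self.T_d, self.n_cycles)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items()})

    def to_file(self, path) -> None:
        lines = []
        for k, v in self.to_dict().items():
            lines.append(f"{k} = {'' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        d: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _TYPES:
                raise ValueError(f"unknown config key {key!r}")
            if val == "" or val == "None":
                d[key] = None
            elif _TYPES[key] is bool:
                d[key] = val.lower() in ("1", "true", "yes")
            else:
                d[key] = _TYPES[key](val)
        return cls.from_dict(d)


def generate_cohort(n: int, rng: np.random.Generator, sampler=None) -> list[Cell]:
    """n cells with i.i.d. baselines from ``sampler`` (default uniform (0,1)).

    ``sampler(rng, n)`` must return an array of values in (0, 1]; the default
    matches the standard initial condition of uniformly distributed regulator
    values. Lineage ids are distinct.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sampler is None:
        k0 = rng.uniform(size=n)
        # uniform(0,1) excludes exact 0 only almost surely; enforce the domain
        k0[k0 == 0.0] = np.nextafter(0.0, 1.0)
    else:
        k0 = np.asarray(sampler(rng, n), dtype=float)
    return [Cell(k0=float(k)) for k in k0]


def _header_lines(config: RunConfig | None, seed: int | None) -> list[str]:
    from . import __version__

    lines = [f"# stochpd {__version__}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if config is not None:
        for k, v in config.to_dict().items():
            lines.append(f"# {k} = {v}")
    return lines


def write_csv(df: pd.DataFrame, path, config: RunConfig | None = None,
              seed: int | None = None) -> None:
    """Write a DataFrame as comma-separated CSV with a ``#`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_json(obj: dict, path, config: RunConfig | None = None,
               seed: int | None = None) -> None:
    """Write a JSON summary with provenance fields embedded."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"stochpd_version": __version__}
    if seed is not None:
        payload["seed"] = seed
    if config is not None:
        payload["config"] = config.to_dict()
    payload.update(obj)
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
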