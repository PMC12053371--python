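"""Core model: parameters, regulator-value trajectories, rate functions.

Every tumour cell carries a scaled regulator value ``k`` in (0, 1] (e.g. a
normalised phosphorylated-ERK level). Drug exposure drives ``k`` down
exponentially with rate ``delta``; between doses ``k`` relaxes back toward the
cell's natural baseline ``k0`` with rate ``alpha``. Cells with ``k`` below
``k_death`` are in the *death pool* and die with rate ``mu``; cells with ``k``
above ``k_div`` are in the *division pool* and divide with rate ``lam``.

The trajectory of ``k`` is deterministic given the dose schedule, so all
stochasticity lives in the death/division events. The functions here give the
trajectory in closed form, the time of entry into the death pool, the hazard
functions, and the exact threshold-crossing times of the piecewise-exponential
trajectory (the backbone of exact event-driven simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import count
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "NEVER",
    "ModelParams",
    "DoseSchedule",
    "Cell",
    "regulator_sustained",
    "time_to_death_pool",
    "death_rate",
    "division_rate",
    "regulator_multidose",
    "threshold_crossings",
]

#: Sentinel for "this time is never reached"; compares greater than any finite time.
NEVER = math.inf

_lineage_counter = count()


@dataclass(frozen=True)
class ModelParams:
    """Rates and thresholds of the cell-population model.

    Parameters
    ----------
    mu : float
        Death rate (per unit time) of cells in the death pool.
    lam : float
        Division rate (per unit time) of cells in the division pool.
    delta : float
        Drug-action rate: exponential decay rate of ``k`` during a dose.
    alpha : float
        Relaxation rate of ``k`` toward its baseline during recovery.
    k_death : float
        Death-pool threshold (cells with ``k < k_death`` may die).
    k_div : float
        Division-pool threshold (cells with ``k > k_div`` may divide).
    death_rate_kind : {"step", "linear"}
        ``"step"``: constant rate ``mu`` below ``k_death``, zero above.
        ``"linear"``: ``mu * max(0, 1 - k/k_death)``, i.e. zero at the
        threshold rising linearly to ``mu`` at ``k = 0``; the slope can be
        scaled via ``linear_slope``.
    linear_slope : float
        Multiplier on the linear variant's slope (1.0 reproduces the default
        form above).
    """

    mu: float = 1.0
    lam: float = 0.4
    delta: float = 2.5
    alpha: float = 2.0
    k_death: float = 0.25
    k_div: float = 0.5
    death_rate_kind: Literal["step", "linear"] = "step"
    linear_slope: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu", "lam", "delta", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0 < self.k_death <= self.k_div < 1):
            raise ValueError(
                f"thresholds must satisfy 0 < k_death <= k_div < 1, "
                f"got k_death={self.k_death}, k_div={self.k_div}"
            )
        if self.death_rate_kind not in ("step", "linear"):
            raise ValueError(f"unknown death_rate_kind {self.death_rate_kind!r}")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DoseSchedule:
    """Drug administration schedule.

    Either a single sustained dose (drug always present), or repeated cycles
    of length ``T``: drug on for ``T_d``, then a recovery period of ``T - T_d``.
    ``n_cycles=None`` means the cycles repeat without bound; after a finite
    number of cycles the drug is never applied again and cells relax toward
    their baselines indefinitely.
    """

    sustained: bool = False
    T: float | None = 3.0
    T_d: float | None = 1.0
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        if not self.sustained:
            if self.T is None or self.T_d is None:
                raise ValueError("cyclic schedule requires T and T_d")
            if not (0 <= self.T_d <= self.T) or self.T <= 0:
                raise ValueError(f"need 0 <= T_d <= T, T > 0; got T_d={self.T_d}, T={self.T}")
            if self.n_cycles is not None and self.n_cycles < 1:
                raise ValueError("n_cycles must be positive or None")

    @classmethod
    def sustained_dose(cls) -> "DoseSchedule":
        return cls(sustained=True, T=None, T_d=None)

    @classmethod
    def cycles(cls, T: float, T_d: float, n_cycles: int | None = None) -> "DoseSchedule":
        return cls(sustained=False, T=T, T_d=T_d, n_cycles=n_cycles)


@dataclass
class Cell:
    """One tumour cell: baseline ``k0``, current regulator value, lineage tag."""

    k0: float
    k: float | None = None
    alive: bool = True
    lineage: int = field(default_factory=lambda: next(_lineage_counter))

    def __post_init__(self) -> None:
        if not (0 < self.k0 <= 1):
            raise ValueError(f"k0 must lie in (0, 1], got {self.k0}")
        if self.k is None:
            self.k = self.k0


def regulator_sustained(k0, t, delta):
    """Regulator value ``k0 * exp(-delta * t)`` under a sustained dose.

    Vectorised in ``k0`` and ``t``.
    """
    k0 = np.asarray(k0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(k0 <= 0) or np.any(k0 > 1):
        raise ValueError("k0 must lie in (0, 1]")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    out = k0 * np.exp(-delta * t)
    return out if out.ndim else float(out)


def time_to_death_pool(k0, delta, k_death=0.25):
    """First time a cell starting at ``k0`` reaches the death pool.

    Returns 0 if the cell starts at or below the threshold, else
    ``log(k0/k_death)/delta``. With ``delta == 0`` and ``k0 > k_death`` the
    pool is never reached and :data:`NEVER` is returned. Vectorised in ``k0``.
    """
    k0 = np.asarray(k0, dtype=float)
    if np.any(k0 <= 0) or np.any(k0 > 1):
        raise ValueError("k0 must lie in (0, 1]")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    below = k0 <= k_death
    if delta == 0:
        out = np.where(below, 0.0, NEVER)
    else:
        with np.errstate(invalid="ignore"):
            out = np.where(below, 0.0, np.log(np.maximum(k0, k_death) / k_death) / delta)
    return out if out.ndim else float(out)


def death_rate(k, params: ModelParams):
    """Death hazard w(k): step function w0 or the linear variant w1.

    At exact threshold equality ``k == k_death`` the cell is counted as *not*
    in the death pool (the step formula uses strict inequalities; this is a
    measure-zero convention). Vectorised in ``k``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    if params.death_rate_kind == "step":
        out = np.where(k < params.k_death, params.mu, 0.0)
    else:
        out = params.mu * np.maximum(
            0.0, params.linear_slope * (1.0 - k / params.k_death)
        )
        out = np.where(k >= params.k_death, 0.0, out)
    return out if out.ndim else float(out)


def division_rate(k, params: ModelParams):
    """Division hazard: ``lam`` for ``k > k_div``, zero otherwise."""
    k = np.asarray(k, dtype=float)
    out = np.where(k > params.k_div, params.lam, 0.0)
    return out if out.ndim else float(out)


def _peak_value(k0: float, n: int, schedule: DoseSchedule, params: ModelParams) -> float:
    """Regulator value at the start of cycle n (closed form of the recurrence)."""
    if n == 0:
        return k0
    a = 1.0 - math.exp(-params.alpha * (schedule.T - schedule.T_d))
    b = math.exp(-params.delta * schedule.T_d) * math.exp(
        -params.alpha * (schedule.T - schedule.T_d)
    )
    if b == 1.0:  # no drug, no relaxation: k never moves
        return k0
    K = a / (1.0 - b) * k0
    return K + (k0 - K) * b**n


def _regulator_multidose_scalar(
    k0: float, t: float, schedule: DoseSchedule, params: ModelParams
) -> float:
    if schedule.sustained:
        return k0 * math.exp(-params.delta * t)
    T, T_d = schedule.T, schedule.T_d
    n = int(math.floor(t / T))
    if schedule.n_cycles is not None and n >= schedule.n_cycles:
        # dosing over: relax toward k0 from the end of the last recovery
        t_end = schedule.n_cycles * T
        k_end = _peak_value(k0, schedule.n_cycles, schedule, params)
        return k0 - (k0 - k_end) * math.exp(-params.alpha * (t - t_end))
    kn = _peak_value(k0, n, schedule, params)
    s = t - n * T
    if s <= T_d:
        return kn * math.exp(-params.delta * s)
    k_d = kn * math.exp(-params.delta * T_d)
    return k0 - (k0 - k_d) * math.exp(-params.alpha * (s - T_d))


def regulator_multidose(k0, t, schedule: DoseSchedule, params: ModelParams):
    """Deterministic regulator trajectory under a cyclic dose/recovery schedule.

    During the n-th dose, ``k(t) = k_n exp(-delta (t - nT))`` where ``k_n`` is
    the peak value at the cycle start; during the n-th recovery,
    ``k(t) = k0 - (k0 - k(nT + T_d)) exp(-alpha (t - nT - T_d))``. Continuous
    in ``t`` and bounded by ``(0, k0]``. Vectorised in ``t``.
    """
    if not (0 < k0 <= 1):
        raise ValueError("k0 must lie in (0, 1]")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.array(
        [_regulator_multidose_scalar(k0, float(ti), schedule, params) for ti in np.atleast_1d(t_arr)]
    )
    if t_arr.ndim == 0:
        return float(out[0])
    return out.reshape(t_arr.shape)


def _dose_down_crossing(k_start: float, threshold: float, delta: float) -> float | None:
    """Time (from segment start) at which k_start e^{-delta s} hits threshold."""
    if k_start <= threshold or delta == 0:
        return None
    return math.log(k_start / threshold) / delta


def _recovery_up_crossing(
    k_start: float, k0: float, threshold: float, alpha: float
) -> float | None:
    """Time (from segment start) at which k0 - (k0-k_start) e^{-alpha s} hits threshold."""
    if k_start > threshold or k0 <= threshold or alpha == 0:
        return None
    return math.log((k0 - k_start) / (k0 - threshold)) / alpha


def threshold_crossings(
    k0: float,
    schedule: DoseSchedule,
    params: ModelParams,
    threshold: float,
    horizon: float,
) -> list[tuple[float, str]]:
    """All times in ``[0, horizon]`` where the deterministic trajectory crosses
    ``threshold``, each solved in closed form within its dose/recovery segment.

    Returns a time-sorted list of ``(time, direction)`` with direction
    ``"down"`` or ``"up"``; directions alternate.
    """
    if not (0 < k0 <= 1):
        raise ValueError("k0 must lie in (0, 1]")
    if not math.isfinite(horizon) or horizon < 0:
        raise ValueError("horizon must be finite and >= 0")
    out: list[tuple[float, str]] = []
    if schedule.sustained:
        s = _dose_down_crossing(k0, threshold, params.delta)
        if s is not None and s <= horizon:
            out.append((s, "down"))
        return out

    T, T_d = schedule.T, schedule.T_d
    n_max = int(math.floor(horizon / T))
    for n in range(n_max + 1):
        if schedule.n_cycles is not None and n >= schedule.n_cycles:
            break
        kn = _peak_value(k0, n, schedule, params)
        # dose phase
        s = _dose_down_crossing(kn, threshold, params.delta)
        if s is not None and s <= T_d:
            t_cross = n * T + s
            if t_cross <= horizon:
                out.append((t_cross, "down"))
        # recovery phase
        k_d = kn * math.exp(-params.delta * T_d)
        s = _recovery_up_crossing(k_d, k0, threshold, params.alpha)
        if s is not None and s <= T - T_d:
            t_cross = n * T + T_d + s
            if t_cross <= horizon:
                out.append((t_cross, "up"))
    if schedule.n_cycles is not None and schedule.n_cycles * T <= horizon:
        # trailing unbounded recovery after the last cycle
        t_end = schedule.n_cycles * T
        k_end = _peak_value(k0, schedule.n_cycles, schedule, params)
        s = _recovery_up_crossing(k_end, k0, threshold, params.alpha)
        if s is not None and t_end + s <= horizon:
            out.append((t_end + s, "up"))
    return out
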