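"""Multiple-dose treatment with recovery periods and cell division.

During each dose the drug drives regulator values down (rate ``delta``);
during each recovery they relax toward the cell's baseline ``k0`` (rate
``alpha``). Cells below ``k_death`` die with rate ``mu``; cells above
``k_div`` divide with rate ``lam``. Because a daughter inherits both her
mother's current regulator value and the founder's baseline, every cell in a
lineage shares the founder's deterministic trajectory, so death and division
hazards are piecewise constant between the analytic threshold crossings of
that trajectory — which makes exact per-cell event sampling possible.

The peak regulator values at cycle starts obey the linear recurrence
``k_{n+1} = a k0 + b k_n`` with ``a = 1 - e^{-alpha (T - T_d)}`` and
``b = e^{-delta T_d} e^{-alpha (T - T_d)}``, converging to the fixed point
``K = a k0/(1 - b)``. Whether repeated dosing eliminates the population is
decided by the per-cycle growth exponent of the fittest lineage at its
asymptotic cycle, ``r(k0) = lam * (division-pool time) - mu * (death-pool
time)``; the critical death rate ``mu_c`` is the root of ``sup_k0 r(k0) = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    ModelParams,
    DoseSchedule,
    _peak_value,
    _regulator_multidose_scalar,
    threshold_crossings,
)
from .simulate import Realisation

__all__ = [
    "PeakSequence",
    "CriticalRateResult",
    "PopulationCapError",
    "peak_recurrence",
    "hazard_segments",
    "simulate_multidose",
    "percycle_occupancy",
    "growth_exponent",
    "estimate_critical_mu",
]

#: sentinel: no finite critical death rate exists
NO_FINITE_MU_C = math.inf


class PopulationCapError(RuntimeError):
    """Raised when a supercritical simulation exceeds the population cap."""


@dataclass(frozen=True)
class PeakSequence:
    """Recurrence coefficients and iterated peak values for one founder."""

    a: float
    b: float
    k: np.ndarray  # k_0 .. k_n
    K: float       # asymptotic peak a k0/(1-b)


def peak_recurrence(
    k0: float, schedule: DoseSchedule, params: ModelParams, n: int
) -> PeakSequence:
    """Iterate the peak-value recurrence ``k_{m+1} = a k0 + b k_m`` for m <= n.

    The iteration and the closed form ``K + (k0 - K) b^m`` agree to machine
    precision; both are exposed via the returned :class:`PeakSequence`.
    """
    if schedule.sustained:
        raise ValueError("peak recurrence is defined for cyclic schedules")
    if n < 0:
        raise ValueError("n must be >= 0")
    a = 1.0 - math.exp(-params.alpha * (schedule.T - schedule.T_d))
    b = math.exp(-params.delta * schedule.T_d) * math.exp(
        -params.alpha * (schedule.T - schedule.T_d)
    )
    ks = np.empty(n + 1)
    ks[0] = k0
    for m in range(n):
        ks[m + 1] = a * k0 + b * ks[m]
    K = k0 if b == 1.0 else a / (1.0 - b) * k0
    return PeakSequence(a=a, b=b, k=ks, K=K)


def hazard_segments(
    k0: float, schedule: DoseSchedule, params: ModelParams, horizon: float
) -> list[tuple[float, float, float, float]]:
    """Piecewise-constant hazards of one lineage's shared trajectory.

    Returns time-sorted segments ``(t0, t1, death_rate, division_rate)``
    covering [0, horizon], with boundaries at dose/recovery switches and at
    the closed-form threshold crossings of ``k_death`` and ``k_div``.
    """
    if params.death_rate_kind != "step":
        raise NotImplementedError(
            "multidose simulation supports the step death rate only"
        )
    bounds = {0.0, horizon}
    if not schedule.sustained:
        T, T_d = schedule.T, schedule.T_d
        n_max = int(math.floor(horizon / T)) + 1
        if schedule.n_cycles is not None:
            n_max = min(n_max, schedule.n_cycles)
        for n in range(n_max):
            if n * T < horizon:
                bounds.add(n * T)
            if n * T + T_d < horizon:
                bounds.add(n * T + T_d)
    for thr in (params.k_death, params.k_div):
        for t, _ in threshold_crossings(k0, schedule, params, thr, horizon):
            if t < horizon:
                bounds.add(t)
    edges = sorted(bounds)
    segs = []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (t0 + t1)
        k_mid = _regulator_multidose_scalar(k0, mid, schedule, params)
        rd = params.mu if k_mid < params.k_death else 0.0
        rb = params.lam if k_mid > params.k_div else 0.0
        segs.append((t0, t1, rd, rb))
    return segs


def _simulate_lineage(
    segs: list[tuple[float, float, float, float]],
    rng: np.random.Generator,
    next_id: int,
    founder_id: int,
    cap_check,
) -> tuple[list[tuple[float, str, int, int]], list[tuple[int, int, float, float]], int]:
    """Simulate all cells of one lineage (LIFO), given shared hazard segments.

    Returns (events, cell records (id, parent, birth, death-or-nan), next_id).
    """
    events: list[tuple[float, str, int, int]] = []
    records: list[tuple[int, int, float, float]] = []
    # stack of (birth_time, cell_id, parent_id)
    stack = [(0.0, founder_id, -1)]
    while stack:
        birth, cid, parent = stack.pop()
        t = birth
        death_time = math.nan
        for t0, t1, rd, rb in segs:
            if t1 <= t:
                continue
            start = max(t, t0)
            h = rd + rb
            seg_end = t1
            while start < seg_end and h > 0:
                wait = rng.exponential(1.0 / h)
                if start + wait >= seg_end:
                    break
                start += wait
                if rng.uniform() < rd / h:
                    events.append((start, "death", cid, parent))
                    death_time = start
                    break
                next_id += 1
                events.append((start, "division", next_id, cid))
                stack.append((start, next_id, cid))
                cap_check()
            if not math.isnan(death_time):
                break
            t = t1
        records.append((cid, parent, birth, death_time))
    return events, records, next_id


def simulate_multidose(
    n: int,
    schedule: DoseSchedule,
    params: ModelParams,
    horizon: float,
    rng: np.random.Generator,
    cap: int = 10**6,
    k0: np.ndarray | None = None,
) -> Realisation:
    """Exact stochastic birth-death simulation under a dose/recovery schedule.

    n founder cells receive i.i.d. uniform baselines (or the supplied ``k0``
    array); every descendant shares its founder's deterministic trajectory.
    Event times are sampled exactly from the piecewise-constant hazards.
    Terminates at extinction or at ``horizon``; raises
    :class:`PopulationCapError` if the number of simultaneously tracked cells
    exceeds ``cap`` (runaway supercritical growth).
    """
    if n < 1 or horizon <= 0:
        raise ValueError("need n >= 1 and horizon > 0")
    if k0 is None:
        k0 = rng.uniform(size=n)
    else:
        k0 = np.asarray(k0, dtype=float)
        if k0.shape != (n,):
            raise ValueError("k0 must have shape (n,)")
    created = n  # total cells ever created, across all lineages

    def cap_check() -> None:
        nonlocal created
        created += 1
        if created > cap:
            raise PopulationCapError(f"population cap {cap} exceeded")

    events: list[tuple[float, str, int, int]] = []
    lineage: list[tuple[int, int, float, float, float]] = []
    streams = rng.spawn(n)
    next_id = n - 1
    for i in range(n):
        segs = hazard_segments(float(k0[i]), schedule, params, horizon)
        ev, rec, next_id = _simulate_lineage(segs, streams[i], next_id, i, cap_check)
        events.extend(ev)
        for cid, parent, birth, death in rec:
            lineage.append((cid, parent, float(k0[i]), birth, death))
    events.sort(key=lambda e: e[0])
    times = np.array([e[0] for e in events])
    kinds = [e[1] for e in events]
    ids = np.array([e[2] for e in events], dtype=int)
    parents = np.array([e[3] for e in events], dtype=int)
    n_alive = sum(1 for rec in lineage if math.isnan(rec[4]))
    return Realisation(
        n0=n,
        times=times,
        kinds=kinds,
        cell_ids=ids,
        parents=parents,
        extinct=(n_alive == 0),
        lineage=lineage,
    )


def percycle_occupancy(
    k0: float,
    schedule: DoseSchedule,
    params: ModelParams,
    cycle: int | None = None,
) -> tuple[float, float]:
    """Time per cycle the deterministic trajectory spends in each pool.

    Returns ``(time below k_death, time above k_div)`` within cycle ``cycle``
    (``None`` = the asymptotic cycle, whose peak is the fixed point K).
    """
    if schedule.sustained:
        raise ValueError("per-cycle occupancy is defined for cyclic schedules")
    T, T_d = schedule.T, schedule.T_d
    delta, alpha = params.delta, params.alpha
    c, d = params.k_death, params.k_div
    if cycle is None:
        kn = peak_recurrence(k0, schedule, params, 0).K
    else:
        if cycle < 0:
            raise ValueError("cycle must be >= 0")
        kn = _peak_value(k0, cycle, schedule, params)

    # --- dose phase: k decays from kn with rate delta
    def time_below_dose(thr: float) -> float:
        if kn <= thr:
            return T_d
        if delta == 0:
            return 0.0
        return max(0.0, T_d - math.log(kn / thr) / delta)

    death_dose = time_below_dose(c)
    div_dose = T_d - time_below_dose(d)

    # --- recovery phase: k rises from k_d toward k0 with rate alpha
    k_d = kn * math.exp(-delta * T_d)
    rec = T - T_d

    def time_below_recovery(thr: float) -> float:
        if k_d >= thr:
            return 0.0
        if k0 <= thr or alpha == 0:
            return rec
        return min(rec, math.log((k0 - k_d) / (k0 - thr)) / alpha)

    death_rec = time_below_recovery(c)
    div_rec = rec - time_below_recovery(d)
    return death_dose + death_rec, div_dose + div_rec


def growth_exponent(
    k0: float, schedule: DoseSchedule, params: ModelParams, mu: float | None = None
) -> float:
    """Asymptotic per-cycle log-growth rate of the lineage founded at ``k0``:
    ``lam * (division-pool time) - mu * (death-pool time)`` at the K-peak cycle."""
    mu = params.mu if mu is None else mu
    t_death, t_div = percycle_occupancy(k0, schedule, params, cycle=None)
    return params.lam * t_div - mu * t_death


@dataclass(frozen=True)
class CriticalRateResult:
    """Outcome of the critical-death-rate search.

    ``mu_c`` is the smallest death rate for which no lineage has a positive
    asymptotic per-cycle growth exponent; ``math.inf`` signals that no finite
    value exists (some lineage never enters the death pool), 0.0 the
    degenerate boundary where any positive rate suffices.
    """

    mu_c: float
    bracket: tuple[float, float]
    tol: float
    sweep_mu: np.ndarray
    sweep_growth: np.ndarray
    note: str = ""


def estimate_critical_mu(
    schedule: DoseSchedule,
    params: ModelParams,
    bracket: tuple[float, float] = (1e-9, 100.0),
    tol: float = 1e-8,
    k0_grid: np.ndarray | None = None,
    sweep_points: int = 21,
) -> CriticalRateResult:
    """Critical death rate mu_c by bisection on the fittest lineage's growth.

    The population growth criterion is ``g(mu) = sup_{k0} [lam * T_div(k0) -
    mu * T_death(k0)]`` with occupancies evaluated at the asymptotic peak
    cycle; g is continuous and non-increasing in mu, and mu_c is its root.
    The supremum is taken over a k0 grid on (0, 1]. If some lineage has zero
    asymptotic death-pool time (so the drug can never kill it), no finite
    mu_c exists and the infinite sentinel is returned.
    """
    if schedule.sustained:
        raise ValueError("mu_c is defined for cyclic schedules")
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError(f"invalid bracket {bracket}")
    if k0_grid is None:
        k0_grid = np.linspace(1e-4, 1.0, 512)
    occ = np.array([percycle_occupancy(k, schedule, params) for k in k0_grid])
    t_death, t_div = occ[:, 0], occ[:, 1]

    def g(mu: float) -> float:
        return float(np.max(params.lam * t_div - mu * t_death))

    sweep_mu = np.linspace(lo, hi, sweep_points)
    sweep_growth = np.array([g(m) for m in sweep_mu])

    if np.any((t_death == 0) & (t_div > 0)) or (
        params.lam == 0 and np.any(t_death == 0)
    ):
        return CriticalRateResult(
            mu_c=NO_FINITE_MU_C, bracket=bracket, tol=tol,
            sweep_mu=sweep_mu, sweep_growth=sweep_growth,
            note="some lineage never enters the death pool: no finite mu_c",
        )
    if g(lo) <= 0:
        return CriticalRateResult(
            mu_c=0.0, bracket=bracket, tol=tol,
            sweep_mu=sweep_mu, sweep_growth=sweep_growth,
            note="growth negative throughout bracket: any mu > 0 gives extinction",
        )
    if g(hi) > 0:
        raise ValueError(
            f"bracket {bracket} does not change sign: g({hi}) = {g(hi):.4g} > 0"
        )
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if g(mid) > 0:
            a = mid
        else:
            b = mid
    return CriticalRateResult(
        mu_c=0.5 * (a + b), bracket=bracket, tol=tol,
        sweep_mu=sweep_mu, sweep_growth=sweep_growth,
    )
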