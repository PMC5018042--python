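"""Impulsive-vaccination simulator and closed-form vaccine kinetics.

Vaccination boosts are instantaneous additions of dose ``V_i`` to the
vaccine compartment at scheduled times (delta-function dosing).  Between
boosts the nondimensional system is integrated with scipy; at a boost time
``t_i`` the vaccine level jumps right-continuously,
``V(t_i+) = V(t_i-) + V_i``, and every other compartment is continuous.
Impulses are realised by stopping and restarting the integrator at boost
times, never by a stiff approximation of the delta functions.

For a strictly periodic schedule (same dose ``V0`` every ``delta_t``,
first boost at t=0) the vaccine level has an exact geometric-sum solution
and a periodic upper envelope ``V_inf``; both are provided in closed form
and serve as oracles for the numerical integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import NondimParameters, Trajectory, rhs_nondim

__all__ = [
    "TreatmentSchedule",
    "SolverSettings",
    "simulate",
    "closed_form_V_impulsive",
    "V_infinity",
]


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered vaccination boosts: times (>= 0, strictly increasing) and
    positive doses.  Boost indexing is 0-based: the boost at ``boost_times[n]``
    is boost ``n``; for the periodic shorthand the first boost (index 0) is
    given at ``start``."""

    boost_times: tuple
    boost_doses: tuple

    def __post_init__(self) -> None:
        times = np.asarray(self.boost_times, float)
        doses = np.asarray(self.boost_doses, float)
        if times.shape != doses.shape:
            raise ValueError("boost_times and boost_doses must have equal length")
        if times.size and (np.any(times < 0) or np.any(np.diff(times) <= 0)):
            raise ValueError("boost times must be >= 0 and strictly increasing")
        if np.any(doses <= 0):
            raise ValueError("boost doses must be positive")
        object.__setattr__(self, "boost_times", tuple(times))
        object.__setattr__(self, "boost_doses", tuple(doses))

    @classmethod
    def empty(cls) -> "TreatmentSchedule":
        return cls((), ())

    @classmethod
    def periodic(cls, V0: float, delta_t: float, n_boosts: int, start: float = 0.0) -> "TreatmentSchedule":
        """Expand the (V0, delta_t, n_boosts) shorthand to explicit lists."""
        if V0 <= 0 or delta_t <= 0 or n_boosts < 1:
            raise ValueError("periodic schedule needs V0 > 0, delta_t > 0, n_boosts >= 1")
        times = start + delta_t * np.arange(n_boosts)
        return cls(tuple(times), (V0,) * int(n_boosts))


@dataclass(frozen=True)
class SolverSettings:
    """Integration controls and the finite surrogates for the asymptotic
    dichotomy: tumour load crossing ``extinction_floor`` counts as cure,
    crossing ``escape_ceiling`` as treatment failure."""

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    horizon: float = 200.0
    escape_ceiling: float = 1e8
    extinction_floor: float = 1e-8
    method: str = "LSODA"
    sample_dt: Optional[float] = None  # uniform output sampling; None = solver steps

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if not self.escape_ceiling > self.extinction_floor > 0:
            raise ValueError("need escape_ceiling > extinction_floor > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    def with_horizon(self, horizon: float) -> "SolverSettings":
        return replace(self, horizon=horizon)


def simulate(
    params: NondimParameters,
    schedule: TreatmentSchedule,
    x0: Sequence[float],
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Integrate the nondimensional system under the boost schedule.

    Returns a :class:`~immunopulse.model.Trajectory` holding both one-sided
    states at every boost instant.  Integration stops early with status
    ``"escape"`` / ``"extinction"`` when the tumour load crosses the
    configured ceiling / floor (crossings are located by solver events).
    """
    y = np.asarray(x0, float).copy()
    if y.shape != (7,):
        raise ValueError("x0 must have 7 components")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError(f"x0 must be finite and nonnegative, got {y}")

    horizon = float(settings.horizon)
    times = [t for t in schedule.boost_times if t <= horizon]
    doses = list(schedule.boost_doses[: len(times)])

    boost_log = []
    t_now = 0.0
    # boost exactly at t=0 folds into the initial condition (right-continuity)
    while times and times[0] <= 0.0:
        times.pop(0)
        d = doses.pop(0)
        y[0] += d
        boost_log.append((0.0, d))

    ts_out = [np.array([t_now])]
    ys_out = [y.copy()[None, :]]
    status = "completed"
    n_steps = 0

    def ceiling_event(t, s, _q):
        return s[6] - settings.escape_ceiling

    ceiling_event.terminal = True
    ceiling_event.direction = 1

    def floor_event(t, s, _q):
        return s[6] - settings.extinction_floor

    floor_event.terminal = True
    floor_event.direction = -1

    segment_ends = times + [horizon]
    seg_doses = doses + [None]

    for t_end, dose in zip(segment_ends, seg_doses):
        if t_end <= t_now:
            if dose is not None:
                y[0] += dose
                boost_log.append((t_end, dose))
                ts_out.append(np.array([t_now]))
                ys_out.append(y.copy()[None, :])
            continue
        if settings.sample_dt is not None:
            n = max(int(math.ceil((t_end - t_now) / settings.sample_dt)), 1)
            t_eval = np.linspace(t_now, t_end, n + 1)
        else:
            t_eval = None
        sol = solve_ivp(
            rhs_nondim,
            (t_now, t_end),
            y,
            args=(params,),
            method=settings.method,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=settings.max_step,
            t_eval=t_eval,
            events=(ceiling_event, floor_event),
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at t={t_now}: {sol.message}")
        n_steps += sol.t.size
        # LSODA may report an internal step a hair past t_end before the
        # clipped endpoint; drop anything outside (t_now, t_end]
        seg_keep = (sol.t > t_now) & (sol.t <= t_end)
        ts_out.append(sol.t[seg_keep])
        ys_out.append(sol.y.T[seg_keep])
        if sol.status == 1:  # terminal event fired
            if sol.t_events[0].size:
                status = "escape"
                ts_out.append(sol.t_events[0])
                ys_out.append(sol.y_events[0])
            else:
                status = "extinction"
                ts_out.append(sol.t_events[1])
                ys_out.append(sol.y_events[1])
            break
        t_now = t_end
        y = sol.y[:, -1].copy()
        if dose is not None:
            y[0] += dose
            boost_log.append((t_end, dose))
            ts_out.append(np.array([t_now]))
            ys_out.append(y.copy()[None, :])

    t_all = np.concatenate(ts_out)
    y_all = np.vstack(ys_out)
    y_all = np.where(np.abs(y_all) < settings.atol, np.maximum(y_all, 0.0), y_all)
    return Trajectory(
        t=t_all,
        y=y_all,
        status=status,
        n_steps=n_steps,
        rtol=settings.rtol,
        atol=settings.atol,
        boost_log=tuple(boost_log),
    )


def closed_form_V_impulsive(t, V0: float, delta_t: float, k_v: float):
    """Exact vaccine level under dose ``V0`` every ``delta_t`` from t=0.

    For ``t`` in the ``n``-th inter-boost interval (``n = floor(t/delta_t)``)
    the accumulated level is the partial geometric sum

        ``V(t) = V0 * (1 - exp(-(n+1) k_v dt)) / (1 - exp(-k_v dt))
                 * exp(-k_v (t - n dt))``.

    At a boost instant the post-boost (right-continuous) value is returned,
    which the same expression yields at ``t = n*delta_t``.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if V0 <= 0 or delta_t <= 0 or k_v <= 0:
        raise ValueError("V0, delta_t and k_v must be positive")
    # snap times within roundoff of a boost instant onto it (right-continuity)
    n = np.floor(t / delta_t + 1e-9)
    q = math.exp(-k_v * delta_t)
    prefactor = V0 * (1.0 - q ** (n + 1)) / (1.0 - q)
    out = prefactor * np.exp(-k_v * (t - n * delta_t))
    return out if out.ndim else float(out)


def V_infinity(t, V0: float, delta_t: float, k_v: float):
    """Limiting periodic vaccine level (upper envelope of the impulsive
    solution): ``V0 * exp(-k_v dt frac(t/dt)) / (1 - exp(-k_v dt))``.

    Periodic with period ``delta_t`` and strictly above
    :func:`closed_form_V_impulsive` for every finite accumulation state.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if V0 <= 0 or delta_t <= 0 or k_v <= 0:
        raise ValueError("V0, delta_t and k_v must be positive")
    frac = t / delta_t - np.floor(t / delta_t + 1e-9)
    frac = np.where(frac < 0, 0.0, frac)  # snapped boost instants
    out = V0 * np.exp(-k_v * delta_t * frac) / (1.0 - math.exp(-k_v * delta_t))
    return out if out.ndim else float(out)
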