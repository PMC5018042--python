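"""Closed-form asymptotic limits, cure thresholds and dosing envelopes.

After a single boost the immune cascade relaxes to steady levels driven
only by the endogenous antigen source ``V_p``; the CTL level settles at

    ``c_inf = mu_D mu_R V_p / (k_CR k_m mu_C mu_R mu_D + k V_p)``

and the tumour equation reduces to a scalar ODE whose positive equilibrium
``p_bar = a c_inf / g - 1`` (when it exists) separates extinction from
escape.  Cure after one boost requires ``g < g_max = a mu_D mu_R / k`` and
``V_p`` above an explicit bound.

Under periodic dosing (dose ``V0`` every ``delta_t``) the vaccine level is
asymptotically trapped between envelopes ``V_m <= V(t) <= V_M``; pushing
the envelopes down the cascade bounds the CTL level in ``[c_min, c_max]``
and yields the threshold band ``[p_bar_min, p_bar_max]`` together with the
minimal curative dose of the periodic regime.

The module also implements the asymptotically periodic solution of a
linearly forced scalar equation ``x' = F(t) - G(t) x`` with period-1
coefficients, which is the mechanism by which every cascade compartment
inherits the dosing period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad, solve_ivp

from .model import NondimParameters

__all__ = [
    "AsymptoticSummary",
    "CureVerdict",
    "DoseDesign",
    "LinearPeriodicForcing",
    "single_boost_limits",
    "single_boost_d_m",
    "p_bar",
    "cure_conditions_single_boost",
    "periodic_envelopes",
    "min_curative_dose",
    "linear_periodic_limit",
    "c_infinity",
    "g_max",
]

#: relative tolerance of k_m ~ k_v degeneracy switching in closed forms
_DEGENERATE_RTOL = 1e-12


def c_infinity(params: NondimParameters) -> float:
    """Limiting CTL level sustained by the endogenous antigen source."""
    q = params
    return (q.mu_D * q.mu_R * q.V_p) / (
        q.k_CR * q.k_m * q.mu_C * q.mu_R * q.mu_D + q.k * q.V_p
    )


def g_max(params: NondimParameters) -> float:
    """Largest tumour growth rate curable by any vaccination regime:
    ``a * mu_D * mu_R / k``."""
    return params.a * params.mu_D * params.mu_R / params.k


@dataclass(frozen=True)
class AsymptoticSummary:
    """Closed-form limits and envelopes; fields that do not apply to the
    requested regime stay ``None``.  Thresholds that come out nonpositive
    are reported as absent (``None``)."""

    c_infinity: Optional[float] = None
    p_bar: Optional[float] = None
    g_max: Optional[float] = None
    d_m_limit: Optional[float] = None
    d_c_limit: Optional[float] = None
    d_r_limit: Optional[float] = None
    r_limit: Optional[float] = None
    V_m: Optional[float] = None
    V_M: Optional[float] = None
    d_m_band: Optional[tuple] = None
    d_c_band: Optional[tuple] = None
    d_r_band: Optional[tuple] = None
    r_band: Optional[tuple] = None
    c_min: Optional[float] = None
    c_max: Optional[float] = None
    p_bar_min: Optional[float] = None
    p_bar_max: Optional[float] = None
    min_curative_dose: Optional[float] = None
    feasible: Optional[bool] = None

    def to_dict(self) -> dict:
        out = {}
        for name, value in self.__dict__.items():
            if value is None:
                continue
            out[name] = list(value) if isinstance(value, tuple) else value
        return out


def single_boost_limits(params: NondimParameters) -> AsymptoticSummary:
    """Long-time limits of the cascade after one boost (driven by ``V_p``).

    Every compartment except the tumour converges: ``d_m -> V_p/k_m``,
    ``d_c -> V_p/(k_m k_CR)``, ``d_r -> V_p/(k_m k_CR mu_D)``,
    ``r -> V_p/(k_m k_CR mu_D mu_R)`` and ``c -> c_inf``.  With ``V_p = 0``
    all limits are zero and the tumour escapes from any positive load.
    """
    q = params
    d_m = q.V_p / q.k_m
    d_c = d_m / q.k_CR
    d_r = d_c / q.mu_D
    r = d_r / q.mu_R
    cinf = c_infinity(q)
    return AsymptoticSummary(
        c_infinity=cinf,
        p_bar=p_bar(q),
        g_max=g_max(q),
        d_m_limit=d_m,
        d_c_limit=d_c,
        d_r_limit=d_r,
        r_limit=r,
    )


def single_boost_d_m(t, V0: float, params: NondimParameters):
    """Mature-DC transient after one boost of ``V0`` at t=0.

    ``d_m(t) = V_p/k_m (1-e^{-k_m t}) + V0 (e^{-k_v t}-e^{-k_m t})/(k_m-k_v)``;
    when ``k_m`` and ``k_v`` coincide (resonant clearance) the boost term
    degenerates to ``V0 t e^{-k_m t}``.
    """
    t = np.asarray(t, float)
    q = params
    base = q.V_p / q.k_m * (1.0 - np.exp(-q.k_m * t))
    if abs(q.k_m - q.k_v) < _DEGENERATE_RTOL * abs(q.k_m):
        boost = V0 * t * np.exp(-q.k_m * t)
    else:
        boost = V0 * (np.exp(-q.k_v * t) - np.exp(-q.k_m * t)) / (q.k_m - q.k_v)
    out = base + boost
    return out if out.ndim else float(out)


def p_bar(params: NondimParameters) -> Optional[float]:
    """Threshold tumour load ``a c_inf / g - 1``; ``None`` when the scalar
    tumour equation has no positive equilibrium (then every positive load
    escapes)."""
    value = params.a * c_infinity(params) / params.g - 1.0
    return value if value > 0 else None


@dataclass(frozen=True)
class CureVerdict:
    """Feasibility of cure after a single boost."""

    feasible: bool
    g_max: float
    V_p_required: float  # inf when g >= g_max
    V_p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cure_conditions_single_boost(params: NondimParameters) -> CureVerdict:
    """Single-boost cure conditions: ``g < g_max`` and endogenous antigen
    ``V_p`` above ``g k_m mu_C mu_D mu_R k_CR / (k (g_max - g))``.  With
    ``V_p = 0`` the cure can never be achieved after one boost."""
    q = params
    gm = g_max(q)
    if q.g >= gm:
        return CureVerdict(False, gm, math.inf, q.V_p)
    bound = q.g * q.k_m * q.mu_C * q.mu_D * q.mu_R * q.k_CR / (q.k * (gm - q.g))
    return CureVerdict(q.V_p > bound, gm, bound, q.V_p)


def periodic_envelopes(params: NondimParameters, V0: float, delta_t: float) -> AsymptoticSummary:
    """Asymptotic envelopes of the cascade under periodic dosing.

    The vaccine level is eventually trapped in ``[V_m, V_M]`` with
    ``V_m = V0 e^{-k_v dt} / (1 - e^{-k_v dt})`` and
    ``V_M = V0 / (1 - e^{-k_v dt})``; the band cascades down by division by
    ``k_m, k_CR, mu_D, mu_R`` and the CTL band is

        ``c_min = d_c^m / (mu_C + k r_M)``,  ``c_max = d_c^M / (mu_C + k r_m)``.

    A nonzero endogenous source simply shifts both vaccine envelopes up by
    ``V_p`` (it adds the same constant forcing to ``d_m``).  Thresholds
    ``p_bar_min/max = a c_min/max / g - 1`` are reported when positive.
    """
    if V0 <= 0 or delta_t <= 0:
        raise ValueError("V0 and delta_t must be positive")
    q = params
    decay = math.exp(-q.k_v * delta_t)
    V_m = V0 * decay / (1.0 - decay) + q.V_p
    V_M = V0 / (1.0 - decay) + q.V_p
    d_m_band = (V_m / q.k_m, V_M / q.k_m)
    d_c_band = (d_m_band[0] / q.k_CR, d_m_band[1] / q.k_CR)
    d_r_band = (d_c_band[0] / q.mu_D, d_c_band[1] / q.mu_D)
    r_band = (d_r_band[0] / q.mu_R, d_r_band[1] / q.mu_R)
    c_min = d_c_band[0] / (q.mu_C + q.k * r_band[1])
    c_max = d_c_band[1] / (q.mu_C + q.k * r_band[0])
    pb_min = q.a * c_min / q.g - 1.0
    pb_max = q.a * c_max / q.g - 1.0
    return AsymptoticSummary(
        g_max=g_max(q),
        V_m=V_m,
        V_M=V_M,
        d_m_band=d_m_band,
        d_c_band=d_c_band,
        d_r_band=d_r_band,
        r_band=r_band,
        c_min=c_min,
        c_max=c_max,
        p_bar_min=pb_min if pb_min > 0 else None,
        p_bar_max=pb_max if pb_max > 0 else None,
    )


@dataclass(frozen=True)
class DoseDesign:
    """Minimal curative periodic dose for a fixed dosing interval."""

    feasible: bool
    g_max: float
    g_max_effective: float  # g_max * exp(-k_v * delta_t)
    dose: Optional[float]  # None when infeasible
    p_bar_min_at_dose: Optional[float]
    delta_t: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def min_curative_dose(params: NondimParameters, delta_t: float) -> DoseDesign:
    """Smallest periodic dose that guarantees cure for small tumours.

    Feasible iff ``g < g_max e^{-k_v dt}``; then

        ``V0* = g k_m k_CR mu_C mu_R mu_D (1 - e^{-k_v dt})
                / (k (g_max e^{-k_v dt} - g))``

    makes ``c_min`` reach ``g/a``.  At exactly ``V0*`` the guaranteed basin
    ``p_bar_min`` is marginal (zero); any dose margin opens it up.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    q = params
    gm = g_max(q)
    decay = math.exp(-q.k_v * delta_t)
    gm_eff = gm * decay
    if q.g >= gm_eff:
        return DoseDesign(False, gm, gm_eff, None, None, delta_t)
    dose = (
        q.g * q.k_m * q.k_CR * q.mu_C * q.mu_R * q.mu_D * (1.0 - decay)
        / (q.k * (gm_eff - q.g))
    )
    env = periodic_envelopes(q, dose, delta_t)
    pb = q.a * env.c_min / q.g - 1.0
    return DoseDesign(True, gm, gm_eff, dose, max(pb, 0.0), delta_t)


class LinearPeriodicForcing:
    """Period-1 coefficients of ``x' = F(t) - G(t) x`` with ``G > 0``.

    On construction the cumulative decay integral is tabulated once with a
    high-accuracy ODE solve, and the one-period constants of the asymptotic
    fixed point are computed by adaptive quadrature:
    ``G_A = int_0^1 G`` and ``K = int_0^1 F(s) e^{-int_s^1 G} ds``.
    """

    def __init__(
        self,
        F: Callable[[float], float],
        G: Callable[[float], float],
        quad_rtol: float = 1e-10,
        check: bool = True,
    ) -> None:
        self.F = F
        self.G = G
        self.quad_rtol = quad_rtol
        if check:
            rng = np.random.default_rng(0)
            for t in rng.uniform(0.0, 1.0, 8):
                if G(t) <= 0:
                    raise ValueError(f"G must be positive on [0,1]; G({t}) = {G(t)}")
                for fn, name in ((F, "F"), (G, "G")):
                    if not math.isclose(fn(t + 1.0), fn(t), rel_tol=1e-8, abs_tol=1e-10):
                        raise ValueError(f"{name} is not period-1 at t={t}")
        sol = solve_ivp(
            lambda t, y: [G(t)],
            (0.0, 1.0),
            [0.0],
            rtol=1e-12,
            atol=1e-14,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"decay-integral tabulation failed: {sol.message}")
        self._cumG = sol.sol
        self.G_A = float(sol.y[0, -1])
        K, err = quad(
            lambda s: F(s) * math.exp(-(self.G_A - self.cum_G(s))),
            0.0,
            1.0,
            epsrel=quad_rtol,
            epsabs=0.0,
            limit=200,
        )
        self.K = K
        self._K_err = err

    def cum_G(self, t: float) -> float:
        """``int_0^t G(u) du`` for t in [0, 1]."""
        return float(self._cumG(t)[0])


def linear_periodic_limit(forcing: LinearPeriodicForcing, t) -> float:
    """Value at ``t`` of the unique period-1 attractor of
    ``x' = F(t) - G(t) x``:

        ``x*(t) = K/(1-e^{-G_A}) e^{-int_0^tau G}
                  + int_0^tau F(s) e^{-int_s^tau G} ds``,  ``tau = t - [t]``.

    Every solution of the forced equation converges to ``x*`` at the
    geometric per-period rate ``e^{-G_A}``.
    """
    tau = float(t) - math.floor(float(t))
    cum_tau = forcing.cum_G(tau)
    head = forcing.K / (1.0 - math.exp(-forcing.G_A)) * math.exp(-cum_tau)
    if tau == 0.0:
        return head
    tail, _ = quad(
        lambda s: forcing.F(s) * math.exp(-(cum_tau - forcing.cum_G(s))),
        0.0,
        tau,
        epsrel=forcing.quad_rtol,
        epsabs=0.0,
        limit=200,
    )
    return head + tail
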