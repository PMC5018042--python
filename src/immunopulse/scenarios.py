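"""Seeded synthetic scenarios spanning the model's qualitative regimes.

No reference parameter values ship with the model (the clinical
calibration lives in prior work), so tests and demos draw nondimensional
rates log-uniformly — by default over [0.05, 5], two decades around unity
on the rescaled clock — and rejection-sample until the drawn set provably
sits in the requested regime:

* ``single_boost_infeasible`` — no endogenous antigen (``V_p = 0``):
  a single boost can never cure, every positive tumour load escapes;
* ``single_boost_cure_feasible`` — ``g < g_max`` and ``V_p`` above the
  cure bound, so loads below ``p_bar`` are eliminated;
* ``periodic_cure`` — ``g < g_max e^{-k_v dt}``; dosing at 1.5x the
  minimal curative dose eliminates loads below ``p_bar_min``;
* ``periodic_escape`` — initial load above ``p_bar_max``, which grows
  without bound despite dosing;
* ``near_separatrix`` — the reduced tumour equation started exactly on
  its separatrix.

The closed-form guarantees behind these regimes hold once the immune
cascade sits inside its asymptotic envelope band, so fixtures start the
immune compartments inside that band (periodic regimes) or at the
``V_p``-driven steady state (single-boost regimes); the band is forward
invariant, which makes each fixture's expected outcome a theorem about
its trajectory rather than a hope.  Each accepted draw additionally
carries a detectability certificate bounding the time to cross the
extinction floor or escape ceiling, so simulations decide in finite time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from . import asymptotics
from .model import NondimParameters
from .simulate import SolverSettings, TreatmentSchedule, simulate

__all__ = [
    "REGIMES",
    "RATE_NAMES",
    "ScenarioSpec",
    "Fixture",
    "draw_nondim_parameters",
    "sample_parameters",
    "make_fixture",
]

REGIMES = (
    "single_boost_cure_feasible",
    "single_boost_infeasible",
    "periodic_cure",
    "periodic_escape",
    "near_separatrix",
)

#: draw order of the nondimensional rates (fixed for reproducibility)
RATE_NAMES = ("k_v", "k_m", "k_CR", "mu_D", "mu_R", "mu_C", "k", "g", "a")

_DEFAULT_RANGE = (0.05, 5.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one seeded scenario draw.

    ``ranges`` overrides the log-uniform bounds per rate name; the dosing
    interval, dose margin over the minimal curative dose and the initial
    load as a fraction of the guaranteed basin are the regime knobs the
    analysis prescribes.
    """

    regime: str
    seed: int
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    delta_t: float = 1.0
    dose_margin: float = 1.5
    load_fraction: float = 0.5
    rejection_budget: int = 5000

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        for name, (lo, hi) in self.ranges.items():
            if name not in RATE_NAMES or not 0 < lo < hi:
                raise ValueError(f"bad range for {name!r}: ({lo}, {hi})")

    def bounds(self, name: str) -> Tuple[float, float]:
        return self.ranges.get(name, _DEFAULT_RANGE)


@dataclass(frozen=True)
class Fixture:
    """A complete runnable case with its provable expected outcome."""

    regime: str
    seed: int
    params: NondimParameters
    schedule: TreatmentSchedule
    x0: np.ndarray
    settings: SolverSettings
    expected_outcome: str
    certificate: Dict[str, float]
    H: Optional[Callable[[float], float]] = None  # reduced kill pressure
    gamma: Optional[float] = None  # separatrix value at phase 0

    def run(self):
        """Simulate the fixture with its own settings."""
        return simulate(self.params, self.schedule, self.x0, self.settings)


def draw_nondim_parameters(rng, spec: Optional[ScenarioSpec] = None, V_p: float = 0.0) -> NondimParameters:
    """One unconditioned log-uniform draw of the 9 nondimensional rates."""
    values = {}
    for name in RATE_NAMES:
        lo, hi = spec.bounds(name) if spec is not None else _DEFAULT_RANGE
        values[name] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return NondimParameters(V_p=V_p, **values)


def _immune_steady_state(params: NondimParameters) -> np.ndarray:
    """Exact V_p-driven steady state of the cascade (zero vaccine, no tumour)."""
    lim = asymptotics.single_boost_limits(params)
    return np.array(
        [0.0, lim.d_m_limit, lim.d_c_limit, lim.d_r_limit, lim.r_limit, lim.c_infinity, 0.0]
    )


def _in_band_state(env: asymptotics.AsymptoticSummary, V_pre_boost: float) -> np.ndarray:
    """Immune state inside the periodic envelope band (vaccine at its
    pre-boost cycle value, cascade at band midpoints, no tumour)."""
    mid = lambda band: 0.5 * (band[0] + band[1])
    return np.array(
        [
            V_pre_boost,
            mid(env.d_m_band),
            mid(env.d_c_band),
            mid(env.d_r_band),
            mid(env.r_band),
            0.5 * (env.c_min + env.c_max),
            0.0,
        ]
    )


_FLOOR = SolverSettings().extinction_floor
_CEILING = SolverSettings().escape_ceiling


def _try_regime(params: NondimParameters, spec: ScenarioSpec):
    """Return the regime certificate for a draw, or None to reject.

    Certificates are fully analytic (closed forms only): the defining
    inequality of the regime plus margin/detectability conditions that
    make the expected outcome provable and observable in finite time.
    """
    q = params
    regime = spec.regime
    if regime == "single_boost_infeasible":
        # with V_p = 0 the no-cure guarantee is unconditional: every draw qualifies
        return {"V_p": 0.0, "g": q.g}

    if regime == "single_boost_cure_feasible":
        verdict = asymptotics.cure_conditions_single_boost(q)
        if q.g >= verdict.g_max:
            return None
        V_p = 2.0 * verdict.V_p_required
        q2 = NondimParameters(**{**_rates(q), "V_p": V_p})
        pb = asymptotics.p_bar(q2)
        if pb is None or pb < 0.3:
            return None
        p0 = spec.load_fraction * pb
        lam = q.g * (pb - p0) / (1.0 + p0)
        T = math.log(p0 / _FLOOR) / lam
        if T > 1200.0:
            return None
        return {
            "g_max": verdict.g_max,
            "V_p_required": verdict.V_p_required,
            "V_p": V_p,
            "p_bar": pb,
            "extinction_time_bound": T,
        }

    design = asymptotics.min_curative_dose(q, spec.delta_t)

    if regime in ("periodic_cure", "near_separatrix"):
        if not design.feasible:
            return None
        dose = spec.dose_margin * design.dose
        env = asymptotics.periodic_envelopes(q, dose, spec.delta_t)
        if env.p_bar_min is None or env.p_bar_min < 0.05:
            return None
        cert = {
            "g_max_effective": design.g_max_effective,
            "min_dose": design.dose,
            "dose": dose,
            "p_bar_min": env.p_bar_min,
        }
        if regime == "periodic_cure":
            p0 = spec.load_fraction * env.p_bar_min
            lam = q.g * (env.p_bar_min - p0) / (1.0 + p0)
            T = math.log(p0 / _FLOOR) / lam
            if T > 1200.0:
                return None
            cert["extinction_time_bound"] = T
        return cert

    if regime == "periodic_escape":
        dose = 1.0
        env = asymptotics.periodic_envelopes(q, dose, spec.delta_t)
        pb_max = env.p_bar_max
        if pb_max is not None and pb_max > _CEILING / 200.0:
            return None
        p0 = 1.0 if pb_max is None else 2.0 * pb_max + 1.0
        # growth rate at loads above p_bar_max is at least g/2 by the margin
        T = math.log(_CEILING / p0) / (0.5 * q.g)
        if T > 1500.0:
            return None
        return {
            "dose": dose,
            "p_bar_max": -1.0 if pb_max is None else pb_max,
            "p0": p0,
            "escape_time_bound": T,
        }

    raise AssertionError(regime)


def _rates(params: NondimParameters) -> dict:
    return {name: getattr(params, name) for name in RATE_NAMES}


def _rejection_sample(spec: ScenarioSpec):
    rng = np.random.default_rng(spec.seed)
    last = None
    for _ in range(spec.rejection_budget):
        params = draw_nondim_parameters(rng, spec)
        cert = _try_regime(params, spec)
        if cert is not None:
            if "V_p" in cert and cert["V_p"] > 0:
                params = NondimParameters(**{**_rates(params), "V_p": cert["V_p"]})
            return params, cert
        last = params
    raise RuntimeError(
        f"rejection budget ({spec.rejection_budget}) exhausted for regime "
        f"{spec.regime!r}: the range bounds conflict with the regime "
        f"inequality (last draw: g={last.g:.3g}, "
        f"g_max={asymptotics.g_max(last):.3g}, k_v={last.k_v:.3g})"
    )


def sample_parameters(spec: ScenarioSpec) -> NondimParameters:
    """Draw parameters provably inside the regime (deterministic per seed)."""
    return _rejection_sample(spec)[0]


def make_fixture(spec: ScenarioSpec) -> Fixture:
    """Bundle parameters, schedule, initial state and the provable outcome."""
    params, cert = _rejection_sample(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    q = params

    if spec.regime == "single_boost_infeasible":
        p0 = math.exp(rng.uniform(math.log(0.1), math.log(10.0)))
        # cap the integrated CTL kill exposure a*V0/(k_v k_m k_CR mu_C) at 0.5
        dose = min(1.0, 0.5 * q.k_v * q.k_m * q.k_CR * q.mu_C / q.a)
        exposure = q.a * dose / (q.k_v * q.k_m * q.k_CR * q.mu_C)
        horizon = 1.2 * (math.log(_CEILING / p0) + exposure) / q.g + 5.0 / q.min_rate
        x0 = np.array([0.0, 0, 0, 0, 0, 0, p0])
        cert = {**cert, "p0": p0, "dose": dose, "kill_exposure": exposure}
        return Fixture(
            spec.regime, spec.seed, params,
            TreatmentSchedule(((0.0,)), ((dose,))),
            x0, SolverSettings(horizon=horizon), "escape", cert,
        )

    if spec.regime == "single_boost_cure_feasible":
        pb = cert["p_bar"]
        p0 = spec.load_fraction * pb
        # probe boost small enough not to perturb the V_p-driven steady state
        max_rate = max(q.k_m, q.k_CR, q.mu_D, q.mu_R, q.mu_C, 1.0)
        dose = 0.01 * q.V_p * q.k_v / max_rate
        x0 = _immune_steady_state(params)
        x0[6] = p0
        horizon = 1.3 * cert["extinction_time_bound"] + 10.0
        cert = {**cert, "p0": p0, "dose": dose}
        return Fixture(
            spec.regime, spec.seed, params,
            TreatmentSchedule(((0.0,)), ((dose,))),
            x0, SolverSettings(horizon=horizon), "extinction", cert,
        )

    if spec.regime in ("periodic_cure", "periodic_escape"):
        dose = cert["dose"]
        env = asymptotics.periodic_envelopes(q, dose, spec.delta_t)
        decay = math.exp(-q.k_v * spec.delta_t)
        V_pre = dose * decay / (1.0 - decay)
        x0 = _in_band_state(env, V_pre)
        if spec.regime == "periodic_cure":
            p0 = spec.load_fraction * env.p_bar_min
            horizon = 1.3 * cert["extinction_time_bound"] + 10.0
            expected = "extinction"
        else:
            p0 = cert["p0"]
            horizon = 1.3 * cert["escape_time_bound"] + 10.0
            expected = "escape"
        x0[6] = p0
        n_boosts = int(math.ceil(horizon / spec.delta_t)) + 1
        schedule = TreatmentSchedule.periodic(dose, spec.delta_t, n_boosts)
        cert = {**cert, "p0": p0}
        return Fixture(
            spec.regime, spec.seed, params, schedule, x0,
            SolverSettings(horizon=horizon), expected, cert,
        )

    # near_separatrix: converge the cascade, tabulate the periodic kill
    # pressure H(t) = a c(t), and start the reduced equation on its threshold
    from .periodic import tumor_field, threshold_curve

    dose = cert["dose"]
    env = asymptotics.periodic_envelopes(q, dose, spec.delta_t)
    decay = math.exp(-q.k_v * spec.delta_t)
    V_pre = dose * decay / (1.0 - decay)
    x0 = _in_band_state(env, V_pre)
    burn_in = max(120.0, 8.0 / q.min_rate)
    n_boosts = int(math.ceil(burn_in / spec.delta_t)) + 1
    schedule = TreatmentSchedule.periodic(dose, spec.delta_t, n_boosts)
    traj = simulate(
        params, schedule, x0,
        SolverSettings(horizon=burn_in, rtol=1e-10, atol=1e-12, sample_dt=spec.delta_t / 400.0),
    )
    H = periodic_kill_pressure(traj, q.a, spec.delta_t)
    curve = threshold_curve(tumor_field(q.g, H), [0.0], rtol=1e-10)
    gamma0 = float(curve.gamma[0])
    x0 = x0.copy()
    x0[6] = gamma0
    cert = {**cert, "gamma": gamma0}
    return Fixture(
        spec.regime, spec.seed, params, schedule, x0,
        SolverSettings(horizon=burn_in), "threshold_periodic", cert,
        H=H, gamma=gamma0,
    )


def periodic_kill_pressure(traj, a: float, delta_t: float = 1.0) -> Callable[[float], float]:
    """Extract the limiting periodic kill pressure ``H(t) = a c(t)`` from a
    converged impulsive trajectory (last full inter-boost period, linearly
    interpolated and prolonged periodically with period ``delta_t``)."""
    t_end = traj.t[-1]
    n_last = math.floor(t_end / delta_t + 1e-9) - 1
    lo, hi = n_last * delta_t, (n_last + 1) * delta_t
    mask = (traj.t >= lo) & (traj.t <= hi)
    ts = traj.t[mask] - lo
    cs = traj.component("c")[mask]
    # deduplicate boost instants for interpolation
    keep = np.concatenate([[True], np.diff(ts) > 0])
    ts, cs = ts[keep], cs[keep]

    def H(t: float) -> float:
        tau = (t / delta_t - math.floor(t / delta_t)) * delta_t
        return a * float(np.interp(tau, ts, cs))

    return H
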