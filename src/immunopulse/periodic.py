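"""Classification machinery for ``x' = x F(t, x)`` with period-1 ``F``
increasing in ``x``.

For such fields the fate of every positive solution is decided by the
one-period mean at zero, ``F_A = int_0^1 F(s, 0) ds``:

* ``F_A > 0``: every positive solution diverges (per-period growth factor
  at least ``e^{F_A}``);
* ``F_A < 0`` and ``F(t, x) -> f(t) > 0`` as ``x -> inf``: there is a
  phase-dependent separatrix ``gamma(t0)`` — initial states below it go
  extinct, states above it escape, and the state on it is the unique
  periodic orbit (a fixed point of the period-return map).

The tumour equation ``x' = x (g - H(t)/(1+x))`` with periodic kill
pressure ``H(t) = a c(t)`` is the model instance of this machinery: its
mean criterion compares ``g`` with ``H_A``, and for constant ``H`` the
separatrix is the classical equilibrium ``H/g - 1``.

"Tends to 0 / infinity" is decided by finite surrogates (extinction floor,
escape ceiling, iteration horizon); a run that decides neither reports
``undetermined``, which is the honest outcome near the separatrix and in
the untreated boundary case ``F_A = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .simulate import SolverSettings

__all__ = [
    "PeriodicScalarField",
    "ClassificationResult",
    "ThresholdCurve",
    "constant_field",
    "sinusoid_offset_field",
    "tumor_field",
    "mean_at_zero",
    "return_map",
    "classify_orbit",
    "threshold_curve",
    "tumor_equation_classify",
    "estimate_period",
]


class PeriodicScalarField:
    """Black-box per-capita growth field ``F(t, x)``, period 1 in ``t``.

    Declared structure (period-1, monotone increasing in ``x``, uniform
    bound, large-``x`` limit ``f(t) > 0``) is spot-checked on random
    samples at construction — callables cannot be certified symbolically,
    so the checks are probabilistic and the residual risk is documented.
    """

    def __init__(
        self,
        F: Callable[[float, float], float],
        increasing_in_x: bool = True,
        bound: Optional[float] = None,
        limit_at_infinity: Optional[Callable[[float], float]] = None,
        check: bool = True,
        check_seed: int = 0,
    ) -> None:
        self.F = F
        self.increasing_in_x = increasing_in_x
        self.bound = bound
        self.limit_at_infinity = limit_at_infinity
        if check:
            rng = np.random.default_rng(check_seed)
            ts = rng.uniform(0.0, 1.0, 12)
            xs = rng.uniform(0.0, 10.0, 12)
            for t, x in zip(ts, xs):
                v = F(t, x)
                if not math.isclose(F(t + 1.0, x), v, rel_tol=1e-8, abs_tol=1e-10):
                    raise ValueError(f"F is not period-1 at (t={t}, x={x})")
                if bound is not None and abs(v) > bound * (1 + 1e-12):
                    raise ValueError(f"|F({t},{x})| = {abs(v)} exceeds declared bound {bound}")
                if increasing_in_x and not F(t, x + rng.uniform(0.1, 2.0)) > v:
                    raise ValueError(f"F is not increasing in x at (t={t}, x={x})")

    def __call__(self, t: float, x: float) -> float:
        return self.F(t, x)


def constant_field(kappa: float) -> PeriodicScalarField:
    """Autonomous constant per-capita rate (closed-form exponential orbits)."""
    return PeriodicScalarField(lambda t, x: kappa, increasing_in_x=False, bound=abs(kappa), check=False)


def sinusoid_offset_field(offset: float, amplitude: float = 1.0, saturating_slope: float = 0.0) -> PeriodicScalarField:
    """``F(t,x) = offset + amplitude sin(2 pi t) + s x/(1+x)``: mean at zero
    equals ``offset`` and the optional saturating term makes it strictly
    increasing in ``x`` while staying uniformly bounded."""
    def F(t, x):
        return offset + amplitude * math.sin(2 * math.pi * t) + saturating_slope * x / (1.0 + x)

    return PeriodicScalarField(
        F,
        increasing_in_x=saturating_slope > 0,
        bound=abs(offset) + abs(amplitude) + abs(saturating_slope),
        limit_at_infinity=(lambda t: offset + amplitude * math.sin(2 * math.pi * t) + saturating_slope),
        check=saturating_slope > 0,
    )


def tumor_field(g: float, H: Callable[[float], float]) -> PeriodicScalarField:
    """Reduced tumour field ``F(t,x) = g - H(t)/(1+x)`` for a period-1
    positive kill pressure ``H`` (in the model, ``H(t) = a c(t)``)."""
    return PeriodicScalarField(
        lambda t, x: g - H(t) / (1.0 + x),
        increasing_in_x=True,
        limit_at_infinity=lambda t: g,
        check=False,
    )


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of orbit classification with the evidence that produced it."""

    verdict: str  # extinction | escape | threshold_periodic | undetermined
    mean_at_zero: float
    final_state: float
    periods_used: int
    iterates: tuple  # sampled return-map iterates

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["iterates"] = list(self.iterates)
        return out


@dataclass(frozen=True)
class ThresholdCurve:
    """Separatrix samples ``gamma(t0)`` on a phase grid, with the achieved
    bisection tolerance and the consistency residual of its periodic
    prolongation (sup distance between the curve and the orbit launched
    from ``gamma(t0_grid[0])``)."""

    t0_grid: np.ndarray
    gamma: np.ndarray
    rtol: float
    residual: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t0": self.t0_grid, "gamma": self.gamma})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def mean_at_zero(field: PeriodicScalarField, n_nodes: int = 4097) -> float:
    """One-period mean of the per-capita rate at vanishing population,
    ``F_A = int_0^1 F(s, 0) ds`` — the sign that decides the trichotomy.

    Composite Simpson on a fine uniform grid: exact to roundoff for smooth
    fields and robust for tabulated (piecewise-linear) kill pressures,
    where adaptive quadrature stalls on the kinks.
    """
    from scipy.integrate import simpson

    s = np.linspace(0.0, 1.0, n_nodes)
    return float(simpson(np.array([field(si, 0.0) for si in s]), x=s))


def return_map(
    field: PeriodicScalarField,
    t0: float,
    x0: float,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> float:
    """Advance ``x' = x F(t, x)`` by one period: returns ``x(t0 + 1)``.

    Positive inputs give positive outputs (solutions through ``x > 0``
    never reach zero in finite time), and the map is strictly increasing
    in ``x0`` by uniqueness of solutions.
    """
    if x0 <= 0:
        raise ValueError("return_map requires x0 > 0")
    sol = solve_ivp(
        lambda t, y: [y[0] * field(t, y[0])],
        (t0, t0 + 1.0),
        [x0],
        rtol=rtol,
        atol=atol * max(x0, 1.0),
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"return-map integration failed: {sol.message}")
    return float(sol.y[0, -1])


_FA_BOUNDARY_TOL = 1e-9


def classify_orbit(
    field: PeriodicScalarField,
    t0: float,
    x0: float,
    settings: SolverSettings = SolverSettings(horizon=1000.0),
    map_rtol: float = 1e-10,
) -> ClassificationResult:
    """Decide the fate of the orbit through ``(t0, x0)``.

    A positive mean at zero settles the matter without simulation (escape).
    Otherwise the period-return map is iterated until the state crosses the
    extinction floor or the escape ceiling; hitting the horizon first
    yields ``undetermined`` (expected near the separatrix and in the
    boundary case ``F_A = 0``, which the theory leaves open).
    """
    if x0 <= 0:
        raise ValueError("classification requires x0 > 0")
    F_A = mean_at_zero(field)
    if F_A > _FA_BOUNDARY_TOL:
        return ClassificationResult("escape", F_A, x0, 0, (x0,))
    horizon = int(settings.horizon)
    x = x0
    iterates = [x0]
    for n in range(1, horizon + 1):
        x = return_map(field, t0, x, rtol=map_rtol)
        if n <= 10 or n % 10 == 0:
            iterates.append(x)
        if x < settings.extinction_floor:
            return ClassificationResult("extinction", F_A, x, n, tuple(iterates))
        if x > settings.escape_ceiling:
            return ClassificationResult("escape", F_A, x, n, tuple(iterates))
    verdict = "undetermined"
    if abs(x - x0) <= 10 * map_rtol * max(x0, 1.0) * horizon:
        verdict = "threshold_periodic"
    return ClassificationResult(verdict, F_A, x, horizon, tuple(iterates))


def threshold_curve(
    field: PeriodicScalarField,
    t0_grid: Sequence[float],
    rtol: float = 1e-8,
    map_rtol: float = 1e-10,
    bracket_limit: float = 1e12,
) -> ThresholdCurve:
    """Locate the separatrix ``gamma(t0)`` on each phase of the grid.

    Requires the mean-at-zero to be negative and the field to stay positive
    for large states (declared via ``limit_at_infinity``); under these
    hypotheses ``x0 -> x(t0+1) - x0`` changes sign exactly once and the
    root is bracketed by geometric expansion (factor 4, up to
    ``bracket_limit``) and polished with Brent's method.
    """
    F_A = mean_at_zero(field)
    if F_A >= 0:
        raise ValueError(f"threshold requires a negative mean at zero, got F_A = {F_A}")
    t0_grid = np.asarray(t0_grid, float)
    gammas = np.empty_like(t0_grid)

    def excess(x0: float, t0: float) -> float:
        return return_map(field, t0, x0, rtol=map_rtol) - x0

    guess = 1.0
    for i, t0 in enumerate(t0_grid):
        lo = hi = guess
        n_expand = 0
        while excess(lo, t0) >= 0:
            lo /= 4.0
            n_expand += 1
            if lo < 1.0 / bracket_limit:
                raise RuntimeError(
                    "no extinction side found down to the bracket limit; "
                    "the field violates the separatrix hypotheses"
                )
        while excess(hi, t0) <= 0:
            hi *= 4.0
            n_expand += 1
            if hi > bracket_limit:
                raise RuntimeError(
                    "no escape side found up to the bracket limit; "
                    "the field violates the separatrix hypotheses"
                )
        gammas[i] = brentq(excess, lo, hi, args=(t0,), rtol=rtol, xtol=1e-300)
        guess = gammas[i]  # warm-start the neighbouring phase

    # consistency of the periodic prolongation: the orbit launched on the
    # curve at the first grid phase must track the curve over a full period
    sol = solve_ivp(
        lambda t, y: [y[0] * field(t, y[0])],
        (t0_grid[0], t0_grid[0] + 1.0),
        [gammas[0]],
        rtol=map_rtol,
        atol=1e-14 * max(gammas[0], 1.0),
        dense_output=True,
        method="LSODA",
    )
    shifted = np.where(t0_grid >= t0_grid[0], t0_grid, t0_grid + 1.0)
    on_orbit = sol.sol(shifted)[0]
    residual = float(np.max(np.abs(on_orbit - gammas) / np.maximum(np.abs(gammas), 1e-300)))
    return ThresholdCurve(t0_grid=t0_grid, gamma=gammas, rtol=rtol, residual=residual)


def tumor_equation_classify(
    H: Callable[[float], float],
    g: float,
    t0: float,
    x0: float,
    settings: SolverSettings = SolverSettings(horizon=1000.0),
) -> ClassificationResult:
    """Trichotomy for the reduced tumour equation ``x' = x(g - H(t)/(1+x))``.

    ``g > H_A`` (mean kill pressure too weak) forces escape for every
    positive load; ``g < H_A`` yields the separatrix regime handled by
    :func:`classify_orbit`; ``g = H_A`` (within tolerance) is reported
    ``undetermined`` — the boundary case is not covered by the theory.
    """
    field = tumor_field(g, H)
    F_A = mean_at_zero(field)  # equals g - H_A
    if abs(F_A) <= _FA_BOUNDARY_TOL * max(1.0, abs(g)):
        return ClassificationResult("undetermined", F_A, x0, 0, (x0,))
    return classify_orbit(field, t0, x0, settings=settings)


def estimate_period(
    t: np.ndarray,
    y: np.ndarray,
    tau_range: tuple = (0.5, 1.5),
    window: float = 8.0,
    n_coarse: int = 2001,
) -> float:
    """Estimate the limiting period of a sampled signal by sup-norm segment
    matching.

    The candidate shift ``tau`` minimising
    ``D(tau) = sup_s |y(s + tau) - y(s)|`` over a window taken from the end
    of the record (where start-up transients have decayed most) is located
    on a coarse grid and refined by golden-section search.  ``D`` has a
    V-shaped minimum at the true period, so the refinement is robust to
    interpolation noise.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tau_lo, tau_hi = tau_range
    span = window + tau_hi
    if t[-1] - t[0] <= span:
        raise ValueError("record too short for the requested window and shifts")
    # uniform resampling (the record may hold duplicate boost instants)
    s0 = t[-1] - span
    grid = np.linspace(s0, t[-1], max(int(span / 0.002), 1000) + 1)
    yg = np.interp(grid, t, y)

    def distance(tau: float) -> float:
        base = np.linspace(s0, s0 + window, 2001)
        return float(np.max(np.abs(np.interp(base + tau, grid, yg) - np.interp(base, grid, yg))))

    taus = np.linspace(tau_lo, tau_hi, n_coarse)
    ds = np.array([distance(tau) for tau in taus])
    i = int(np.argmin(ds))
    lo = taus[max(i - 1, 0)]
    hi = taus[min(i + 1, n_coarse - 1)]
    # golden-section refinement on the V-shaped objective
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c1 = b - phi * (b - a)
    c2 = a + phi * (b - a)
    f1, f2 = distance(c1), distance(c2)
    for _ in range(60):
        if f1 < f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - phi * (b - a)
            f1 = distance(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + phi * (b - a)
            f2 = distance(c2)
        if b - a < 1e-10:
            break
    return 0.5 * (a + b)
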