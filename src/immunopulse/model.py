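"""Core tumour-immune model: parameter records, right-hand sides and the
dimensional-to-nondimensional bridge.

The model describes a one-way signalling cascade triggered by tumour
antigen.  Vaccine antigen ``V`` (plus a constant endogenous source ``V_p``)
drives maturation of dendritic cells (``D_m``), which migrate to lymph
nodes and become functional antigen-presenting cells (``D_C``).  Functional
DCs recruit tumour-killing cytotoxic T lymphocytes (CTLs, ``C``) and, after
exhausting into a regulatory phenotype (``D_R``), also recruit regulatory T
cells (Tregs, ``R``) that inactivate CTLs.  The tumour load ``P`` grows
exponentially and is killed by CTLs through a saturating law.

Two equivalent formulations are provided:

* the *dimensional* system with 14 rate/scale parameters plus ``V_p``;
* the *nondimensional* system with 9 rate parameters plus ``V_p``, obtained
  by linear rescaling of the state variables (time is not rescaled).

:func:`nondimensionalize` and :func:`map_state` are the only sanctioned
bridges between the two; parameters are kept in separate flat records so
units can never silently mix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

__all__ = [
    "STATE_NAMES_DIMENSIONAL",
    "STATE_NAMES_NONDIM",
    "DimensionalParameters",
    "NondimParameters",
    "StateVector",
    "Trajectory",
    "rhs_dimensional",
    "rhs_nondim",
    "nondimensionalize",
    "map_state",
    "map_state_inverse",
]

#: Column order used everywhere for the dimensional state.
STATE_NAMES_DIMENSIONAL = ("V", "D_m", "D_C", "D_R", "R", "C", "P")
#: Column order used everywhere for the nondimensional state.
STATE_NAMES_NONDIM = ("V", "d_m", "d_c", "d_r", "r", "c", "p")


def _maybe_float(x):
    """Return float(x), or None when x is symbolic / not coercible."""
    try:
        return float(x)
    except (TypeError, ValueError):
        return None


def _check_positive(name: str, value, allow_zero: bool = False) -> None:
    v = _maybe_float(value)
    if v is None:  # symbolic entry: skip numeric validation
        return
    if not np.isfinite(v):
        raise ValueError(f"parameter {name} must be finite, got {value!r}")
    if allow_zero:
        if v < 0:
            raise ValueError(f"parameter {name} must be >= 0, got {value!r}")
    elif v <= 0:
        raise ValueError(f"parameter {name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class DimensionalParameters:
    """Rates and scales of the dimensional 7-compartment system.

    Attributes
    ----------
    k_l : antigen-driven DC maturation rate (1/time)
    n_V : vaccine amount taken up per maturing DC (amount/cell)
    k_m : mature-DC migration rate to lymph nodes (1/time)
    alpha_l : probability that a migrating DC arrives functional, in (0, 1]
    k_CR : functional-to-regulatory DC transition rate (1/time)
    mu_D : regulatory-DC death rate (1/time)
    a_R : Treg recruitment rate per regulatory DC (1/time)
    mu_R : Treg death rate (1/time)
    a_C : CTL recruitment rate per functional DC (1/time)
    mu_C : CTL death rate (1/time)
    k_R : Treg-mediated CTL inactivation coefficient (1/(cell*time))
    g : tumour growth rate (1/time)
    a_P : CTL kill-rate coefficient (1/(time*cell))
    h_p : tumour-load scale of kill saturation (cells)
    V_p : endogenous antigen source (amount/time), >= 0
    """

    k_l: float
    n_V: float
    k_m: float
    alpha_l: float
    k_CR: float
    mu_D: float
    a_R: float
    mu_R: float
    a_C: float
    mu_C: float
    k_R: float
    g: float
    a_P: float
    h_p: float
    V_p: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name), allow_zero=(f.name == "V_p"))
        al = _maybe_float(self.alpha_l)
        if al is not None and al > 1:
            raise ValueError(f"alpha_l must lie in (0, 1], got {self.alpha_l!r}")
        km, kl, nv = map(_maybe_float, (self.k_m, self.k_l, self.n_V))
        if None not in (km, kl, nv) and abs(km - kl * nv) <= 1e-12 * abs(km):
            warnings.warn(
                "k_m equals k_l*n_V (vaccine decay rate): the mature-DC "
                "response is resonant and closed forms use their degenerate "
                "t*exp branch",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NondimParameters:
    """Rates of the nondimensional system (same time unit as dimensional).

    ``k_v`` is the vaccine clearance rate, ``k`` the lumped Treg-suppression
    coefficient, ``a`` the lumped CTL kill coefficient; the remaining six
    carry over from the dimensional record unchanged.
    """

    k_v: float
    k_m: float
    k_CR: float
    mu_D: float
    mu_R: float
    mu_C: float
    k: float
    g: float
    a: float
    V_p: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name), allow_zero=(f.name == "V_p"))
        kv, km = _maybe_float(self.k_v), _maybe_float(self.k_m)
        if None not in (kv, km) and abs(km - kv) <= 1e-12 * abs(km):
            warnings.warn(
                "k_m equals k_v: mature-DC closed forms use the degenerate "
                "t*exp branch",
                stacklevel=2,
            )

    @property
    def min_rate(self) -> float:
        """Slowest linear rate of the immune cascade (sets settling times)."""
        return min(self.k_v, self.k_m, self.k_CR, self.mu_D, self.mu_R, self.mu_C)


@dataclass(frozen=True)
class StateVector:
    """One snapshot of the 7 compartments (either unit convention).

    Fields follow the nondimensional naming; :func:`map_state` converts a
    dimensional array to this scale.
    """

    V: float
    d_m: float
    d_c: float
    d_r: float
    r: float
    c: float
    p: float

    def to_array(self) -> np.ndarray:
        return np.array([self.V, self.d_m, self.d_c, self.d_r, self.r, self.c, self.p], float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StateVector":
        arr = np.asarray(arr, float)
        if arr.shape != (7,):
            raise ValueError(f"state must have 7 components, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"state must be finite, got {arr}")
        if np.any(arr < 0):
            raise ValueError(f"state must be nonnegative, got {arr}")
        return cls(*arr)


@dataclass(frozen=True)
class Trajectory:
    """Time grid + state samples produced by the simulator.

    Boost instants appear twice in ``t`` (pre- and post-boost state), so the
    grid is non-decreasing rather than strictly increasing.  ``status`` is
    one of ``"completed"``, ``"escape"``, ``"extinction"``.
    """

    t: np.ndarray
    y: np.ndarray  # shape (len(t), 7), columns per STATE_NAMES_NONDIM
    status: str
    n_steps: int
    rtol: float
    atol: float
    boost_log: tuple  # (time, dose) actually applied

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) < 0):
            raise ValueError("trajectory times must be non-decreasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.column_stack([self.t, self.y]), columns=("t",) + STATE_NAMES_NONDIM
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def component(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES_NONDIM.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]


def _reject_nonfinite(state) -> None:
    arr = np.asarray(state)
    if arr.dtype.kind == "f" and not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite state passed to right-hand side: {arr}")


def rhs_dimensional(t, state, params: DimensionalParameters):
    """Time derivative of the dimensional system at ``state``.

    ``state`` is ordered per :data:`STATE_NAMES_DIMENSIONAL`.  The CTL kill
    term saturates in tumour load: ``a_P * h_p * C * P / (h_p + P)``.
    Accepts symbolic entries (plain arithmetic only), in which case the
    finiteness check is skipped.
    """
    _reject_nonfinite(state)
    V, Dm, Dc, Dr, R, C, P = state
    q = params
    dV = -q.k_l * q.n_V * V
    dDm = q.k_l * (V + q.V_p) - q.k_m * Dm
    dDc = q.alpha_l * q.k_m * Dm - q.k_CR * Dc
    dDr = q.k_CR * Dc - q.mu_D * Dr
    dR = q.a_R * Dr - q.mu_R * R
    dC = q.a_C * Dc - q.mu_C * C - q.k_R * C * R
    dP = q.g * P - q.a_P * q.h_p * C * P / (q.h_p + P)
    return np.asarray([dV, dDm, dDc, dDr, dR, dC, dP])


def rhs_nondim(t, state, params: NondimParameters):
    """Time derivative of the nondimensional system at ``state``.

    ``state`` is ordered per :data:`STATE_NAMES_NONDIM`; tumour dynamics is
    ``p' = g*p - a*c*p/(1+p)`` so the tumour grows exponentially at rate
    ``g`` whenever CTLs are absent.
    """
    _reject_nonfinite(state)
    V, dm, dc, dr, r, c, p = state
    q = params
    dV = -q.k_v * V
    ddm = V + q.V_p - q.k_m * dm
    ddc = dm - q.k_CR * dc
    ddr = dc - q.mu_D * dr
    dr_ = dr - q.mu_R * r
    dc_ = dc - q.mu_C * c - q.k * c * r
    dp = q.g * p - q.a * c * p / (1 + p)
    return np.asarray([dV, ddm, ddc, ddr, dr_, dc_, dp])


def nondimensionalize(params: DimensionalParameters) -> NondimParameters:
    """Collapse the 14 dimensional parameters to the 9 nondimensional rates.

    The lumped rates are ``k_v = k_l*n_V``, ``k = alpha_l*k_l*k_m*k_CR*a_R*k_R``
    and ``a = a_P*a_C*alpha_l*k_m*k_l``; ``k_m, k_CR, mu_D, mu_R, mu_C, g``
    and ``V_p`` carry over unchanged.
    """
    q = params
    return NondimParameters(
        k_v=q.k_l * q.n_V,
        k_m=q.k_m,
        k_CR=q.k_CR,
        mu_D=q.mu_D,
        mu_R=q.mu_R,
        mu_C=q.mu_C,
        k=q.alpha_l * q.k_l * q.k_m * q.k_CR * q.a_R * q.k_R,
        g=q.g,
        a=q.a_P * q.a_C * q.alpha_l * q.k_m * q.k_l,
        V_p=q.V_p,
    )


def _state_scales(params: DimensionalParameters) -> np.ndarray:
    """Divisors mapping a dimensional state to the nondimensional scale."""
    q = params
    base = q.alpha_l * q.k_l * q.k_m
    return np.array(
        [
            1.0,  # V unchanged
            q.k_l,  # d_m = D_m / k_l
            base,  # d_c = D_C / (alpha_l k_l k_m)
            base * q.k_CR,  # d_r
            base * q.k_CR * q.a_R,  # r
            base * q.a_C,  # c
            q.h_p,  # p = P / h_p
        ]
    )


def map_state(state, params: DimensionalParameters) -> np.ndarray:
    """Rescale a dimensional state array to nondimensional variables."""
    return np.asarray(state, float) / _state_scales(params)


def map_state_inverse(state, params: DimensionalParameters) -> np.ndarray:
    """Rescale a nondimensional state array back to dimensional variables."""
    return np.asarray(state, float) * _state_scales(params)
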