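# Methods

## Model and assumptions

The package implements a compartmental model of vaccination immunotherapy
in which injected tumour antigen triggers a strictly feed-forward immune
cascade: antigen -> mature dendritic cells -> functional antigen-presenting
cells -> {CTL recruitment, regulatory-DC exhaustion -> Treg recruitment ->
CTL inactivation}.  Two structural assumptions carry all of the analysis:

1. **The cascade is one-way.**  No compartment is influenced by the tumour
   load, so the five linear immune equations can be solved independently
   and the tumour then obeys a scalar non-autonomous equation
   `p' = p (g - a c(t)/(1+p))`.
2. **Boosts are impulsive.**  A vaccination adds its dose to the vaccine
   compartment instantaneously (right-continuous jump); between boosts the
   smooth vector field applies.  The simulator realises this by stopping
   and restarting the integrator at boost times — never by approximating
   delta functions with stiff pulses — so boost handling is exact up to the
   integrator tolerance.

Two parameterisations exist.  The dimensional record carries the 14
original rates/scales plus the endogenous source `V_p`; the nondimensional
record carries 9 rates plus `V_p`.  The reduction rescales only the state
variables (the clock is unchanged), so nondimensional rates are directly
comparable with dimensional time constants.  `nondimensionalize` and
`map_state` are the only bridges, and parameters live in separate frozen
records so unit systems cannot silently mix.  Two notational wrinkles of
the source model are resolved in code: the kill-term saturation scale is a
single symbol (upper/lower-case variants denote the same quantity — the
nondimensional form `a·c·p/(1+p)` forces this), and the lumped kill
coefficient uses the migration success probability `alpha_l` (the only
migration probability in the model).  The narrative description of Treg-
mediated CTL inactivation names the DC-exhaustion rate, but the equations
use a separate coefficient; the equations are taken as authoritative.

## Parameters

All nondimensional rates are per unit time on the model clock.  No
clinical calibration is shipped (the original estimates belong to prior
patient-fitting work and are not reproduced here); instead the scenario
module draws each rate log-uniformly from [0.05, 5] — two decades centred
on unity, wide enough to create genuine time-scale separation between the
vaccine, dendritic-cell and lymphocyte compartments without making the
system unintegrably stiff.  `V_p` defaults to 0, the regime of the
original clinical model (endogenous antigen response fully suppressed).

Solver defaults: LSODA with `rtol = 1e-8`, `atol = 1e-10`; closed-form
comparisons in the tests tighten these to `1e-10`–`1e-11`.  The
asymptotic dichotomy "tends to 0 / to infinity" is made decidable in
finite time by surrogates: extinction floor `1e-8` and escape ceiling
`1e8` on the tumour load, horizon 200 time units (simulation) or 1000
return-map iterations (scalar classification), all overridable.  A run
that decides neither reports `undetermined` — the honest outcome near the
separatrix and in the boundary case where growth exactly balances the mean
kill pressure, which the theory does not cover.

## Closed forms and numerics

* **Vaccine kinetics.**  Periodic dosing gives the accumulated geometric
  sum `V(t) = V0 (1-q^{n+1})/(1-q) e^{-k_v(t-n dt)}` with `q = e^{-k_v dt}`
  and its periodic envelope `V_inf`.  Times within one part in `1e9` of a
  boost instant are snapped onto it so the right-continuous convention
  survives floating-point division; boost indices are 0-based.
* **Degenerate rates.**  When `k_m` equals `k_v` to within `1e-12`
  relative, the two-exponential mature-DC transient degenerates to
  `V0 t e^{-k_m t}`; the closed form switches branch there and parameter
  construction emits a warning.
* **Linearly forced periodic limit.**  For `x' = F(t) - G(t) x` with
  period-1 coefficients the attracting periodic solution is evaluated from
  the one-period constants `G_A` (cumulative decay, tabulated once by a
  `rtol 1e-12` ODE solve) and `K` (adaptive quadrature, relative tolerance
  `1e-10`).  Convergence toward it is geometric at rate `e^{-G_A}` per
  period, which the tests verify directly.
* **Mean at zero.**  Computed by composite Simpson on 4097 uniform nodes
  rather than adaptive quadrature: kill pressures extracted from
  simulations are piecewise linear, and adaptive rules stall on their
  kinks while Simpson is exact to roundoff there and for smooth fields.
* **Separatrix location.**  For each phase, the fixed point of the
  period-return map is bracketed by geometric expansion (factor 4, bracket
  capped at `1e12` before declaring the field outside the hypotheses) and
  polished with Brent's method at relative tolerance `1e-8` (tighter on
  request).  The curve's consistency is reported as the sup-norm distance
  between the bisected values and the one orbit launched from the first
  grid phase; because the periodic orbit is unstable, a threshold accurate
  to `1e-10` still drifts off after a few hundred iterations — stationarity
  on the separatrix is therefore only observable over moderate horizons,
  and tests use horizons of a few tens of periods for that check.
* **Structural checks are probabilistic.**  Periodicity, monotonicity in
  the state, and declared bounds of user-supplied fields are spot-checked
  on random samples at construction; a black-box callable cannot be
  certified symbolically, and the uniform large-state limit in particular
  is only sampled, a residual risk the caller accepts.
* **Period estimation.**  The limiting period of an oscillating component
  is the shift minimising the sup-norm distance between time-shifted
  segments, using a window at the end of the record (where start-up
  transients are smallest), a coarse scan over [0.5, 1.5] and golden-
  section refinement; the objective is V-shaped at the true period, which
  makes the refinement robust to interpolation noise.

## Synthetic scenarios: what they emulate and what they prove

The scenario generator stands in for the unavailable clinical parameter
sets.  Each regime rejection-samples draws until its defining inequality
holds and the expected outcome is *provable* for the emitted fixture:

* the closed-form cure/escape guarantees hold once the immune cascade sits
  inside its asymptotic envelope band, so periodic fixtures start with the
  vaccine compartment on its exact limiting cycle and the cascade at band
  midpoints — the band is forward-invariant, making the guarantee valid
  from `t = 0` — and single-boost fixtures start at the exact
  `V_p`-driven steady state with a probe boost small enough (scaled by
  `k_v` over the fastest cascade rate) not to perturb it materially;
* margin certificates (threshold at least 0.3 for single-boost cure, 0.05
  for the periodic basin) keep fixtures away from marginal geometries;
* detectability certificates bound the time to cross the extinction floor
  or escape ceiling analytically (decay rate at least
  `g (p_bar - p0)/(1+p0)` below threshold, growth at least `g/2` above
  twice the failure threshold, and an integrated-kill-exposure bound
  `a V0/(k_v k_m k_CR mu_C)` for untreatable draws), so every fixture
  carries a horizon within which its fate must appear.

These choices mean a passing fixture suite demonstrates that simulation
and closed-form analysis agree *where the analysis makes a claim*.  It
does not demonstrate anything about induction-phase transients from a
treatment-naive immune state (where the sufficient conditions are silent
and either fate can occur transiently), about parameter regions near the
separatrix, or about real patients — the rates are synthetic, `V_p = 0`
is an idealisation, and no pharmacokinetic realism beyond impulsive
dosing is attempted.

## Problem sizes

Module tests use 20–40 random draws per property and simulation horizons
of 10–120 time units; the end-to-end checks use 50 single-boost scenarios
per arm, 20 periodic fixtures per arm, 20 reduced-versus-full concordance
scenarios, 100 random dosing triples for the vaccine closed forms, and a
200-period simulation (sampled at 0.01) for the period estimate.  The
acceptance script reproduces that last computation from a command-line
seed.

## Known limitations

* Fields with period other than 1 must be rescaled by the caller; the
  dosing interval is likewise normalised to 1 in the reduced-equation
  workflow (general `delta_t` is supported by the simulator and the
  envelope formulas).
* The boundary cases `F_A = 0` / `g = H_A` are reported `undetermined` by
  design; no attempt is made to resolve them numerically.
* Closed-form transients are provided only for the mature-DC compartment;
  deeper cascade compartments are handled by their limits and by
  simulation (their explicit transients add nothing to the asymptotics).
* Parameter estimation, PSA calibration and stochastic or delayed model
  variants are out of scope.
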