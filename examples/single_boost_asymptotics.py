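"""Closed-form fate of the immune cascade after a single vaccination boost.

With a constant endogenous antigen source V_p the cascade settles at
explicit levels, the CTL compartment at c_inf, and the tumour then obeys a
scalar equation with threshold p_bar = a*c_inf/g - 1: loads below it are
eliminated, loads above it escape.  Cure after one boost needs g below
g_max = a*mu_D*mu_R/k AND V_p above an explicit bound — with V_p = 0 a
single boost can never cure.
"""

from immunopulse import (
    NondimParameters,
    cure_conditions_single_boost,
    single_boost_limits,
)

params = NondimParameters(
    k_v=1.0, k_m=0.8, k_CR=1.2, mu_D=0.9, mu_R=1.1, mu_C=0.7,
    k=1.0, g=0.2, a=2.0, V_p=3.0,
)

limits = single_boost_limits(params)
print(f"steady mature DCs      d_m -> {limits.d_m_limit:.4f}")
print(f"steady functional DCs  d_c -> {limits.d_c_limit:.4f}")
print(f"steady regulatory DCs  d_r -> {limits.d_r_limit:.4f}")
print(f"steady Tregs           r   -> {limits.r_limit:.4f}")
print(f"steady CTL level       c   -> {limits.c_infinity:.4f}")
print(f"tumour threshold       p_bar = {limits.p_bar:.4f}")

verdict = cure_conditions_single_boost(params)
print(f"\nmax curable growth rate g_max = {verdict.g_max:.4f}  (here g = {params.g})")
print(f"endogenous antigen needed: V_p > {verdict.V_p_required:.4f}  (here V_p = {params.V_p})")
print(f"single-boost cure feasible: {verdict.feasible}")
print("\nLoads below p_bar are eliminated; above it the tumour escapes.")
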