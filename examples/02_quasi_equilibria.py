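"""Quasi-equilibria of the fast cell dynamics and the slow resource flow.

Cell populations equilibrate within months while the resource accumulates
over years, so the tumor's state is well described by fixed points of the
cell dynamics at frozen R.  This script prints the three communities'
closed-form abundances at several resource levels, and the induced slow
flow dR/dt on each branch.
"""

from metaniche import (CellType, NoFeasibleEquilibriumError,
                       coexistence_equilibrium, published_defaults,
                       single_type_equilibrium, slow_resource_flow)

params = published_defaults()

for R in (0.0, 1e5, 1e7):
    print(f"\nfrozen resource R = {R:g}:")
    ch = single_type_equilibrium(CellType.CHEATER, R, params)
    pr = single_type_equilibrium(CellType.LOCAL, R, params)
    print(f"  cheater-only   n00* = {ch.abundance(CellType.CHEATER):12.4g}"
          f"   dR/dt = {slow_resource_flow(R, params, ch.resident_set):10.4g}")
    print(f"  producer-only  n10* = {pr.abundance(CellType.LOCAL):12.4g}"
          f"   dR/dt = {slow_resource_flow(R, params, pr.resident_set):10.4g}")
    co = coexistence_equilibrium(R, params)
    if co is None:
        print("  coexistence    infeasible (theta*K1 > K0: cheaters excluded)")
    else:
        print(f"  coexistence    n00* = {co.abundance(CellType.CHEATER):.4g}, "
              f"n10* = {co.abundance(CellType.LOCAL):.4g}")

print("\nSlope of the producer-branch flow is g*beta1 - l ="
      f" {params.g * params.beta1 - params.l:+.4f}/day > 0:"
      "\nthe resource keeps accumulating and never equilibrates on "
      "tumor-growth timescales.")
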