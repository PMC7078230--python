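"""Critical fractional order: where the stability ray crosses the eigenpair.

The worked examples themselves have negative Jacobian trace at
coexistence, so no critical order exists for them; a mild modification
(double the carrying capacity, nearly remove harvesting) flips the trace
positive, and the closed-form theta0 is then cross-checked against a
grid + bisection root of the crossing function p(theta).
"""

import fracprey as fp
from fracprey.model import ModelParams

for name, params in (("example 7.1", fp.example_7_1()), ("example 7.2", fp.example_7_2())):
    ha = fp.critical_order(params)
    print(f"{name}: alpha = {ha.alpha:.6f}, beta = {ha.beta:.6f}, "
          f"applicable = {ha.applicable}")
    print(f"  reason: {ha.reason}")

d = fp.example_7_1().as_dict()
d.update(kappa=2.0, rho1=1e-6)
mod = ModelParams(**d)
ha = fp.critical_order(mod)
eq = fp.interior_equilibrium(mod)
J = fp.jacobian(mod, eq.as_tuple())
print(f"\nmodified set (kappa=2, rho1=1e-6): alpha = {ha.alpha:.4f} > 0, "
      f"complex pair, theta0 = {ha.theta0:.6f}")
print(f"bisection root of p(theta):          {fp.scan_theta(J):.6f}")
print(f"transversality dp/dtheta = {fp.transversality(J):.6f} (pi/2, exact)")
print(f"stable at theta0-0.01: {fp.classify_interior_eq(mod, ha.theta0 - 0.01).label}")
print(f"unstable at theta0+0.01: {fp.classify_interior_eq(mod, ha.theta0 + 0.01).label}")

# Below theta0 the coexistence state attracts; above it the complex pair
# enters the instability sector and a fractional Hopf bifurcation occurs.
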