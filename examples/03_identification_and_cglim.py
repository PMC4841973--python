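"""The APC identification problem, made concrete.

Fits one table under three different adjacent-equality constraints
(CGLIM) and under the intrinsic estimator.  The coefficient vectors
disagree - they differ along the design kernel B0 - while every
estimable quantity (fitted counts, deviance) agrees to machine
precision.  This is why CGLIM conclusions can hinge on an arbitrary
constraint choice, and what the intrinsic estimator's canonical
identification avoids.
"""

import numpy as np

from apcie import (
    ConstraintSpec,
    SyntheticSpec,
    constraint_sensitivity,
    fit_ie,
    simulate,
)

spec = SyntheticSpec(
    a=6, p=5,
    alpha=np.linspace(-0.9, 0.9, 6),   # strong linear age trend
    beta=np.array([-0.2, -0.1, 0.0, 0.1, 0.2]),
    gamma=np.linspace(0.4, -0.4, 10),
    exposures=1e6, seed=5,
)
table = simulate(spec)

out = constraint_sensitivity(table, [
    ConstraintSpec("age", (1, 2)),
    ConstraintSpec("period", (1, 2)),
    ConstraintSpec("cohort", (1, 2)),
])
print("per-effect dispersion across identifications:")
print(out["effects"].to_string(index=False,
                               float_format=lambda x: f"{x:8.3f}"))
print(f"\nfitted-count dispersion (estimable control): "
      f"{out['fitted_count_dispersion']:.2e}")
print(f"deviances across identifications: "
      f"{[round(d, 10) for d in out['deviances']]}")

ie = fit_ie(table)
print("\nCoefficient ranges above are large where the truth has a strong "
      "linear trend, yet fitted counts and deviance are identical: all "
      "identifications differ only along the kernel direction B0 "
      f"(|theta_IE . B0| = {abs(ie.theta @ ie.design.B0):.1e} for the IE).")
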