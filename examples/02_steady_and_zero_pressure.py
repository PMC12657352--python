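"""Steady solves under different outlet boundary conditions.

Solves the healthy template with the empirical healthy-subject flow
division prescribed, then with zero-pressure outlets, and prints both
divisions side by side.  Zero-pressure outlets let the internal
geometric resistance alone set the split, which grossly over-perfuses
the short, wide supra-aortic branches — the motivating failure mode
for resistance-based outflow modelling.
"""

from aortaflow import (build_healthy_template, empirical_division,
                       solve_steady, solve_zero_pressure)
from aortaflow.steady import BCMode, OutletBC

net = build_healthy_template()
q_in = 250.0  # mean systolic inflow, mL/s

division = empirical_division(net)
bcs = {b: OutletBC(BCMode.PRESCRIBED_FRACTION, division[b])
       for b in net.outlets}
res = solve_steady(net, q_in, bcs)
_, zp_division = solve_zero_pressure(net, q_in)

print(f"inlet flow {q_in:.0f} mL/s")
print(f"{'branch':>6} {'empirical %':>12} {'zero-pressure %':>16} "
      f"{'dP mmHg':>9}")
for b in sorted(net.outlets):
    print(f"{b:>6} {100 * division[b]:12.1f} {100 * zp_division[b]:16.1f} "
          f"{res.dP[b]:9.4f}")
print(f"sum of zero-pressure fractions: {sum(zp_division.values()):.12f}")
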