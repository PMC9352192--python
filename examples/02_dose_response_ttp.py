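"""Time to progression as a function of drug dose for all four regimes.

For each canonical case the script computes the exact TTP across a dose
grid and reports the dose-response shape: where TTP peaks, its value at
the maximum tolerated dose, and whether more drug is always better.
"""

import numpy as np

from stemflux import canonical_case, default_initial_state, ttp_dose_curve
from stemflux.fixtures import DEFAULT_HORIZON

x0 = default_initial_state()
m = np.linspace(0.0, 100.0, 101)

print(f"{'case':^4} {'regime':^28} {'argmax dose':>11} {'max t_P':>9} "
      f"{'t_P @ MTD':>10}")
for cid in "ABCD":
    case = canonical_case(cid)
    curve = ttp_dose_curve(case.pharmacodynamics, x0, m, DEFAULT_HORIZON)
    print(f"{cid:^4} {case.regime:^28} {curve.argmax_dose:>10.0f}% "
          f"{curve.max_t_P:>9.1f} {curve.t_P[-1]:>10.1f}")

print(
    "\nTimes are in the model's arbitrary units (rates ~0.1-0.3 per unit)."
    "\nCases A and C (low potency of stemness induction) peak at an interior"
    "\ndose: pushing past it shortens remission because the drug now converts"
    "\nsensitive cells to the resistant state faster than it kills them."
    "\nCases B and D are monotone — the maximum tolerated dose is optimal —"
    "\nand low induction efficacy (C, D) gives the longest delay at MTD."
)
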