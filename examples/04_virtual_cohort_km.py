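"""Simulate a virtual clinical trial and summarize Kaplan-Meier curves.

Samples patients whose basal rates vary uniformly around the baseline,
computes each patient's exact time to progression at several fixed doses,
and averages cohort-level progression-free curves.  A scaled-down ensemble
(10 cohorts x 200 patients) keeps the run short; the full analysis uses
100 cohorts of 1000 patients.
"""

import numpy as np

from stemflux import (
    CohortConfig,
    PatientDistributions,
    aggregate_cohorts,
    canonical_case,
    default_initial_state,
    simulate_cohorts,
)
from stemflux.fixtures import BASELINE, DEFAULT_HORIZON

case = canonical_case("A")
x0 = default_initial_state()
dists = PatientDistributions.from_baseline(BASELINE)  # +/-20% uniform

cfg = CohortConfig(
    n_p=200, n_c=10,
    doses=np.array([20.0, 30.0, 50.0, 100.0]),
    t_grid=np.linspace(0.0, 400.0, 9),
    horizon=DEFAULT_HORIZON, seed=2022, N0=x0.N,
)
result = simulate_cohorts(cfg, dists, case.pharmacodynamics)
ensemble = aggregate_cohorts(result)

print(f"Case {case.case_id}: mean progression-free fraction "
      f"({cfg.n_c} cohorts x {cfg.n_p} patients)")
print("   t  " + " ".join(f"m={m:3.0f}%" for m in ensemble.doses))
for j, t in enumerate(ensemble.t_grid):
    row = "  ".join(f"{ensemble.mean[i, j]:.3f}" for i in range(len(ensemble.doses)))
    print(f"{t:5.0f}  {row}")

print(
    "\nEach column is a Kaplan-Meier curve at a fixed dose. Note the"
    "\nnon-monotone ordering: at late times the 30% dose keeps more"
    "\npatients progression-free than the full dose, because MTD drives"
    "\nsensitive cells into the resistant state. The per-patient optimum"
    "\nsurvives averaging over a heterogeneous cohort."
)
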