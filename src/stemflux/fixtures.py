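"""Canonical parameter bundles for the four pharmacodynamic regimes.

The four cases span the 2x2 design of efficacy (E_SR) and potency
(EC50 P_SR) of stemness induction relative to fixed kill curves:

    A: high efficacy, low potency   (E_SR = 0.2,  P_SR = 50)
    B: high efficacy, high potency  (E_SR = 0.2,  P_SR = 10)
    C: low efficacy,  low potency   (E_SR = 0.02, P_SR = 50)
    D: low efficacy,  high potency  (E_SR = 0.02, P_SR = 10)

All other parameters are shared across cases.  The shared baseline below is
this package's documented default set (see docs/methods.md for the
calibration rationale); it is chosen so that

  * at m = 0 the extinction state is an unstable node (untreated growth),
  * Cases A and C show an interior TTP maximum below the MTD,
  * Cases B and D are monotone non-decreasing in dose with argmax at MTD,
  * the maximum TTP in Case C exceeds those of Cases A and B, and the TTP
    at MTD is larger at low induction efficacy (C, D) than high (A, B).

Every value is config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TumorState, ValidationError
from .pharmacodynamics import LogisticResponse, PharmacodynamicSet

__all__ = [
    "CanonicalCase",
    "canonical_case",
    "default_pharmacodynamics",
    "default_initial_state",
    "BASELINE",
    "CASE_TABLE",
    "DEFAULT_HORIZON",
]

#: version stamp for the default parameter set; bump on any change
BASELINE_VERSION = "1.0"

#: Shared baseline parameters (rates in 1/time, arbitrary time units;
#: doses in % of MTD).  Kill-curve EC50s (P_S = P_R = 20) sit well below the
#: low-potency induction EC50 (P_SR = 50), so that in Cases A and C the drug
#: kills at doses where it does not yet induce stemness.
BASELINE: dict = {
    "b_S": 0.2,       # division rate, sensitive cells
    "b_R": 0.1,       # division rate, resistant (fitness cost: b_R < b_S)
    "k_RS": 0.01,     # backflow (resensitization) rate, dose-independent
    "delta_S": 0.05,  # basal death rate, sensitive (= delta_R)
    "delta_R": 0.05,
    "kappa": 0.01,    # basal stemness-induction rate
    "E_S": 0.3,       # kill efficacy on sensitive cells
    "E_R": 0.03,      # kill efficacy on resistant cells (<< E_S)
    "r_S": 0.3,       # kill-curve saturation rates (1/dose)
    "r_R": 0.3,
    "P_S": 20.0,      # kill-curve EC50s (% MTD)
    "P_R": 20.0,
    "r_SR": 0.3,      # induction-curve saturation rate
    "N0": 1.0e9,      # tumor size at detection (cells)
    "resistant_fraction": 0.01,  # fraction of resistant cells at detection
}

#: default TTP search horizon: ~10x the longest canonical-case TTP (~240)
DEFAULT_HORIZON = 2500.0

#: (E_SR, P_SR, regime label) per case
CASE_TABLE: dict[str, tuple[float, float, str]] = {
    "A": (0.2, 50.0, "high efficacy, low potency"),
    "B": (0.2, 10.0, "high efficacy, high potency"),
    "C": (0.02, 50.0, "low efficacy, low potency"),
    "D": (0.02, 10.0, "low efficacy, high potency"),
}


@dataclass(frozen=True)
class CanonicalCase:
    """One of the four canonical stemness-induction regimes."""

    case_id: str
    E_SR: float
    P_SR: float
    pharmacodynamics: PharmacodynamicSet
    regime: str


def default_pharmacodynamics(
    *, E_SR: float, P_SR: float, baseline: dict | None = None
) -> PharmacodynamicSet:
    """Build a PharmacodynamicSet from the baseline with the given
    stemness-induction efficacy and EC50."""
    p = dict(BASELINE)
    if baseline:
        p.update(baseline)
    return PharmacodynamicSet(
        ds_curve=LogisticResponse(delta=p["delta_S"], E=p["E_S"],
                                  r=p["r_S"], P=p["P_S"]),
        dr_curve=LogisticResponse(delta=p["delta_R"], E=p["E_R"],
                                  r=p["r_R"], P=p["P_R"]),
        ksr_curve=LogisticResponse(delta=p["kappa"], E=E_SR,
                                   r=p["r_SR"], P=P_SR),
        b_S=p["b_S"],
        b_R=p["b_R"],
        k_RS=p["k_RS"],
    )


def default_initial_state(baseline: dict | None = None) -> TumorState:
    """Tumor state at detection: N0 cells split by the resistant fraction."""
    p = dict(BASELINE)
    if baseline:
        p.update(baseline)
    f = p["resistant_fraction"]
    if not 0 <= f < 1:
        raise ValidationError(f"resistant fraction must lie in [0, 1), got {f}")
    return TumorState(x1=p["N0"] * (1.0 - f), x2=p["N0"] * f, t=0.0)


def canonical_case(case_id: str, baseline: dict | None = None) -> CanonicalCase:
    """Return the canonical bundle for case A, B, C or D."""
    key = str(case_id).upper()
    if key not in CASE_TABLE:
        raise ValidationError(
            f"unknown case {case_id!r}; expected one of {sorted(CASE_TABLE)}"
        )
    E_SR, P_SR, regime = CASE_TABLE[key]
    return CanonicalCase(
        case_id=key,
        E_SR=E_SR,
        P_SR=P_SR,
        pharmacodynamics=default_pharmacodynamics(
            E_SR=E_SR, P_SR=P_SR, baseline=baseline
        ),
        regime=regime,
    )
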