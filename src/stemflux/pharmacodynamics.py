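"""Logistic dose-response layer mapping drug dose to rate constants.

Treatment enters the population model through three of the six rates: the
death rates d_S, d_R and the stemness-induction rate k_SR all increase with
drug dose m (expressed as % of the maximum tolerated dose, 0 <= m <= 100)
following a logistic law

    rate(m) = delta + E / (1 + exp(-r (m - P)))

with basal rate delta, efficacy E (the maximal drug-induced increment),
saturation rate r and EC50 P (the dose of half-maximal effect, inversely
related to potency).  Division rates b_S, b_R and the backflow rate k_RS do
not respond to the drug.

The double-edged-sword structure of cytotoxic therapy lives in the relative
shapes of the kill curves d_S(m), d_R(m) and the induction curve k_SR(m):
a drug that kills well may simultaneously push surviving cells into the
resistant, stem-like state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import RateConstants, ValidationError

__all__ = [
    "LogisticResponse",
    "PharmacodynamicSet",
    "validate_dose",
    "logistic_response",
    "rates_at_dose",
    "dose_response_table",
    "default_dose_grid",
]

#: warn when the resistant kill efficacy exceeds this fraction of the
#: sensitive one — the model's notion of "drug resistance" assumes E_R << E_S
E_RATIO_WARN = 0.5


@dataclass(frozen=True)
class LogisticResponse:
    """Four-parameter logistic dose-response curve for one rate constant.

    Parameters
    ----------
    delta
        Basal rate at zero drug effect (1/time); the m -> -inf asymptote.
    E
        Efficacy: maximum drug-induced increment (1/time).
    r
        Saturation rate (1/dose); steepness of the sigmoid.
    P
        EC50 (dose units, % of MTD) — the dose of half-maximal effect.
    """

    delta: float
    E: float
    r: float
    P: float

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValidationError(f"delta must be > 0, got {self.delta}")
        if self.E <= 0:
            raise ValidationError(f"E must be > 0, got {self.E}")
        if self.r <= 0:
            raise ValidationError(f"r must be > 0, got {self.r}")
        if not 0 < self.P <= 100:
            raise ValidationError(f"P must lie in (0, 100], got {self.P}")

    def __call__(self, m):
        return logistic_response(self, m)

    def to_dict(self) -> dict:
        return {"delta": self.delta, "E": self.E, "r": self.r, "P": self.P}


@dataclass(frozen=True)
class PharmacodynamicSet:
    """Full dose-dependent parameterization of the two-state model.

    Bundles the three logistic curves (for d_S, d_R, k_SR) with the three
    dose-independent rates (b_S, b_R, k_RS).  Model assumptions enforced
    here: b_S > b_R (fitness cost of resistance in the absence of drug) and
    delta_S = delta_R (equal basal death rates).  E_R << E_S encodes
    resistance to killing; a warning is issued when E_R >= 0.5 E_S.
    """

    ds_curve: LogisticResponse
    dr_curve: LogisticResponse
    ksr_curve: LogisticResponse
    b_S: float
    b_R: float
    k_RS: float

    def __post_init__(self) -> None:
        if self.b_S <= 0 or self.b_R <= 0 or self.k_RS <= 0:
            raise ValidationError("b_S, b_R and k_RS must all be strictly positive")
        if not self.b_S > self.b_R:
            raise ValidationError(
                f"fitness cost of resistance requires b_S > b_R, "
                f"got b_S={self.b_S}, b_R={self.b_R}"
            )
        if not math.isclose(self.ds_curve.delta, self.dr_curve.delta,
                            rel_tol=1e-12, abs_tol=0.0):
            raise ValidationError(
                "equal basal death rates required: delta_S must equal delta_R"
            )
        if not self.dr_curve.E < self.ds_curve.E:
            raise ValidationError(
                f"resistance requires E_R < E_S, got E_R={self.dr_curve.E}, "
                f"E_S={self.ds_curve.E}"
            )
        if self.dr_curve.E >= E_RATIO_WARN * self.ds_curve.E:
            warnings.warn(
                f"E_R = {self.dr_curve.E} is not << E_S = {self.ds_curve.E} "
                f"(ratio >= {E_RATIO_WARN}); the resistant state is only "
                "weakly protected",
                stacklevel=2,
            )

    def with_induction(self, *, E_SR: float | None = None,
                       P_SR: float | None = None) -> "PharmacodynamicSet":
        """Copy with the stemness-induction efficacy and/or EC50 replaced."""
        kwargs = {}
        if E_SR is not None:
            kwargs["E"] = E_SR
        if P_SR is not None:
            kwargs["P"] = P_SR
        return replace(self, ksr_curve=replace(self.ksr_curve, **kwargs))

    def to_dict(self) -> dict:
        return {
            "b_S": self.b_S,
            "b_R": self.b_R,
            "k_RS": self.k_RS,
            "d_S": self.ds_curve.to_dict(),
            "d_R": self.dr_curve.to_dict(),
            "k_SR": self.ksr_curve.to_dict(),
        }


def validate_dose(m) -> np.ndarray | float:
    """Check doses lie within [0, 100] % of MTD; return as float/array."""
    arr = np.asarray(m, dtype=float)
    if arr.size == 0:
        raise ValidationError("dose grid must be non-empty")
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValidationError(f"dose must lie within [0, 100] % of MTD, got {m!r}")
    return float(arr) if arr.ndim == 0 else arr


def logistic_response(curve: LogisticResponse, m):
    """Evaluate delta + E / (1 + exp(-r (m - P))) at dose(s) m.

    Strictly increasing in m and bounded in (delta, delta + E); point-
    symmetric about the midpoint (P, delta + E/2).
    """
    m = validate_dose(m)
    return curve.delta + curve.E / (1.0 + np.exp(-curve.r * (m - curve.P)))


def rates_at_dose(pd_set: PharmacodynamicSet, m: float) -> RateConstants:
    """Evaluate all six rate constants at a single dose m."""
    m = validate_dose(m)
    if np.ndim(m) != 0:
        raise ValidationError("rates_at_dose takes a scalar dose; use "
                              "dose_response_table for grids")
    return RateConstants(
        b_S=pd_set.b_S,
        b_R=pd_set.b_R,
        d_S=float(logistic_response(pd_set.ds_curve, m)),
        d_R=float(logistic_response(pd_set.dr_curve, m)),
        k_SR=float(logistic_response(pd_set.ksr_curve, m)),
        k_RS=pd_set.k_RS,
    )


def default_dose_grid(n: int = 101) -> np.ndarray:
    """Equally spaced dose grid on [0, 100] % of MTD (default 101 points)."""
    if n < 1:
        raise ValidationError("dose grid needs at least one point")
    return np.linspace(0.0, 100.0, n)


def dose_response_table(pd_set: PharmacodynamicSet, m_grid) -> pd.DataFrame:
    """Tabulate the dose-dependent rates and the growth/switching diagnostics.

    One row per dose with the evaluated rates, the net growth rates
    g_S = b_S - d_S(m) and g_R = b_R - d_R(m), and the two aggregates whose
    competition shapes the dose-response of time to progression: the total
    growth rate g_S + g_R (strictly decreasing in m) and the total switching
    rate k_SR + k_RS (strictly increasing in m).
    """
    m = np.atleast_1d(validate_dose(m_grid))
    d_S = logistic_response(pd_set.ds_curve, m)
    d_R = logistic_response(pd_set.dr_curve, m)
    k_SR = logistic_response(pd_set.ksr_curve, m)
    g_S = pd_set.b_S - d_S
    g_R = pd_set.b_R - d_R
    return pd.DataFrame(
        {
            "m": m,
            "d_S": d_S,
            "d_R": d_R,
            "k_SR": k_SR,
            "g_S": g_S,
            "g_R": g_R,
            "g_S_plus_g_R": g_S + g_R,
            "k_SR_plus_k_RS": k_SR + pd_set.k_RS,
        }
    )
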