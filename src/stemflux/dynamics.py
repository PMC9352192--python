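"""Linear two-state tumor population dynamics.

The model tracks sensitive (x1) and resistant (x2) tumor cells that divide,
die, and interconvert at constant per-capita rates.  The state obeys

    dx/dt = A x,   A = [[b_S - d_S - k_SR,  k_RS],
                        [k_SR,              b_R - d_R - k_RS]]

where b are division rates, d total death rates, k_SR the sensitive-to-
resistant (stemness induction) rate and k_RS the resensitization "backflow"
rate.  Because both off-diagonal entries are strictly positive, A always has
two distinct real eigenvalues and a strictly positive dominant eigenvector,
and the closed-form solution is a sum of two exponential modes.

The only fixed point is extinction (x = 0); its stability — unstable node,
stable node, or saddle — decides whether the tumor grows unchecked, dies
out, or transiently regresses before regrowing (the relapse scenario).

All rates carry units of 1/time in arbitrary time units.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "RateConstants",
    "TumorState",
    "SystemMatrix",
    "EigenStructure",
    "StabilityClass",
    "StabilityLabel",
    "build_system_matrix",
    "eigenstructure",
    "classify_stability",
    "saddle_ratio_condition",
    "solve_trajectory",
    "trajectory_frame",
]

#: relative tolerance below which an eigenvalue counts as numerically zero
DEGENERATE_RTOL = 1e-12


class ValidationError(ValueError):
    """Raised when inputs violate a model contract."""


@dataclass(frozen=True)
class RateConstants:
    """Per-capita rates (1/time) defining the system matrix at a fixed dose.

    Parameters
    ----------
    b_S, b_R
        Division rates of sensitive and resistant cells.
    d_S, d_R
        Total death rates of sensitive and resistant cells under treatment.
    k_SR
        Sensitive -> resistant transition (stemness induction) rate.
    k_RS
        Resistant -> sensitive backflow (resensitization) rate.

    All six rates must be strictly positive.  Internal helpers may build
    instances through :meth:`unchecked` to probe analytic limits (e.g. a
    decoupled single-type population) that the public contract excludes.
    """

    b_S: float
    b_R: float
    d_S: float
    d_R: float
    k_SR: float
    k_RS: float

    def __post_init__(self) -> None:
        for name in ("b_S", "b_R", "d_S", "d_R", "k_SR", "k_RS"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValidationError(
                    f"rate constant {name} must be strictly positive and finite, "
                    f"got {value!r}"
                )

    @classmethod
    def unchecked(cls, b_S, b_R, d_S, d_R, k_SR, k_RS) -> "RateConstants":
        """Bypass positivity validation (test/analysis helper only)."""
        obj = object.__new__(cls)
        for name, value in zip(
            ("b_S", "b_R", "d_S", "d_R", "k_SR", "k_RS"),
            (b_S, b_R, d_S, d_R, k_SR, k_RS),
        ):
            object.__setattr__(obj, name, float(value))
        return obj

    @property
    def g_S(self) -> float:
        """Net growth rate of sensitive cells, b_S - d_S."""
        return self.b_S - self.d_S

    @property
    def g_R(self) -> float:
        """Net growth rate of resistant cells, b_R - d_R."""
        return self.b_R - self.d_R

    def to_dict(self) -> dict:
        return {
            "b_S": self.b_S,
            "b_R": self.b_R,
            "d_S": self.d_S,
            "d_R": self.d_R,
            "k_SR": self.k_SR,
            "k_RS": self.k_RS,
        }


@dataclass(frozen=True)
class TumorState:
    """Population state: x1 sensitive cells, x2 resistant cells, at time t."""

    x1: float
    x2: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValidationError(
                f"cell counts must be non-negative, got x1={self.x1}, x2={self.x2}"
            )

    @property
    def N(self) -> float:
        """Total number of cells."""
        return self.x1 + self.x2

    def as_vector(self) -> np.ndarray:
        return np.array([self.x1, self.x2], dtype=float)


@dataclass(frozen=True)
class SystemMatrix:
    """Entries of the 2x2 rate matrix A (all 1/time)."""

    a11: float
    a12: float
    a21: float
    a22: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=float)

    @property
    def trace(self) -> float:
        return self.a11 + self.a22

    @property
    def det(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    @property
    def discriminant(self) -> float:
        """(a11 - a22)^2 + 4 a12 a21; positive whenever a12 a21 > 0."""
        return (self.a11 - self.a22) ** 2 + 4.0 * self.a12 * self.a21


@dataclass(frozen=True)
class EigenStructure:
    """Spectral decomposition of A together with the initial-condition expansion.

    Eigenvectors are unit Euclidean norm with first nonzero component
    positive.  The coefficients satisfy c1*v1 + c2*v2 = x(0); the products
    c1*(v1_1 + v1_2) and c2*(v2_1 + v2_2) — the mode amplitudes of the total
    population N(t) — are invariant to the normalization choice.
    """

    lambda1: float
    lambda2: float
    v1: np.ndarray
    v2: np.ndarray
    c1: float
    c2: float

    @property
    def alpha1(self) -> float:
        """Amplitude of the growing/dominant mode in N(t) = a1 e^{l1 t} + a2 e^{l2 t}."""
        return self.c1 * (self.v1[0] + self.v1[1])

    @property
    def alpha2(self) -> float:
        """Amplitude of the subdominant mode in N(t)."""
        return self.c2 * (self.v2[0] + self.v2[1])

    def to_dict(self) -> dict:
        return {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "v1": [float(self.v1[0]), float(self.v1[1])],
            "v2": [float(self.v2[0]), float(self.v2[1])],
            "c1": self.c1,
            "c2": self.c2,
        }


class StabilityLabel(str, Enum):
    UNSTABLE_NODE = "UNSTABLE_NODE"
    STABLE_NODE = "STABLE_NODE"
    SADDLE = "SADDLE"
    DEGENERATE = "DEGENERATE"


_INTERPRETATION = {
    StabilityLabel.UNSTABLE_NODE: "unchecked growth",
    StabilityLabel.STABLE_NODE: "extinction",
    StabilityLabel.SADDLE: "regression-then-regrowth",
    StabilityLabel.DEGENERATE: "boundary case",
}


@dataclass(frozen=True)
class StabilityClass:
    """Stability of the extinction fixed point x = 0.

    ``ratio_condition`` reports whether the fitness-ratio form of the saddle
    criterion holds (see :func:`saddle_ratio_condition`); it is ``None``
    outside that criterion's domain (g_R <= 0).
    """

    label: StabilityLabel
    lambda1: float
    lambda2: float
    ratio_condition: bool | None

    @property
    def interpretation(self) -> str:
        return _INTERPRETATION[self.label]


def build_system_matrix(rates: RateConstants) -> SystemMatrix:
    """Assemble the 2x2 rate matrix A from the six rate constants."""
    return SystemMatrix(
        a11=rates.b_S - rates.d_S - rates.k_SR,
        a12=rates.k_RS,
        a21=rates.k_SR,
        a22=rates.b_R - rates.d_R - rates.k_RS,
    )


def _eigenpairs(A: SystemMatrix) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Closed-form eigenvalues/vectors of a real 2x2 matrix with real spectrum.

    With a12 > 0 the vector (a12, lam - a11) is a right eigenvector for
    eigenvalue lam and already has positive first component, matching the
    documented sign convention after unit normalization.
    """
    disc = A.discriminant
    if disc <= 0:
        # excluded by the SystemMatrix invariant a12*a21 > 0
        raise ArithmeticError(
            f"non-positive discriminant {disc}; matrix outside model class"
        )
    half_gap = 0.5 * np.sqrt(disc)
    mean = 0.5 * A.trace
    lam1, lam2 = mean + half_gap, mean - half_gap

    def vec(lam: float) -> np.ndarray:
        # choose the better-conditioned of the two analytic eigenvector forms
        v_a = np.array([A.a12, lam - A.a11])
        v_b = np.array([lam - A.a22, A.a21])
        v = v_a if np.linalg.norm(v_a) >= np.linalg.norm(v_b) else v_b
        v = v / np.linalg.norm(v)
        nz = v[np.nonzero(v)[0][0]]
        return v if nz > 0 else -v

    return lam1, lam2, vec(lam1), vec(lam2)


def eigenstructure(A: SystemMatrix, x0: TumorState) -> EigenStructure:
    """Eigen-decompose A and expand the initial condition in the eigenbasis.

    Returns eigenvalues ordered lambda1 >= lambda2, unit eigenvectors with
    first nonzero component positive, and coefficients (c1, c2) solving
    ``c1*v1 + c2*v2 = x(0)``.
    """
    if x0.N <= 0:
        raise ValidationError("initial state must have N(0) > 0")
    lam1, lam2, v1, v2 = _eigenpairs(A)
    V = np.column_stack([v1, v2])
    c1, c2 = np.linalg.solve(V, x0.as_vector())
    return EigenStructure(
        lambda1=lam1, lambda2=lam2, v1=v1, v2=v2, c1=float(c1), c2=float(c2)
    )


def saddle_ratio_condition(rates: RateConstants) -> bool | None:
    """Fitness-ratio form of the saddle criterion.

    The extinction state is a saddle iff det(A) < 0, which for g_R > 0 is
    algebraically equivalent to

        g_S / g_R > (g_S - k_SR) / k_RS

    i.e. the relative fitness of the sensitive phenotype exceeds its relative
    net outflow.  The equivalence follows from expanding
    det(A) = g_S*g_R - g_S*k_RS - g_R*k_SR and dividing by g_R*k_RS > 0;
    when g_R <= 0 the division flips (or degenerates) and the ratio form no
    longer tracks the determinant sign, so None is returned there.
    """
    g_S, g_R = rates.g_S, rates.g_R
    if g_R <= 0:
        return None
    return g_S / g_R > (g_S - rates.k_SR) / rates.k_RS


def classify_stability(rates: RateConstants) -> StabilityClass:
    """Classify the extinction fixed point from the eigenvalue signs.

    An eigenvalue within ``DEGENERATE_RTOL * max(|lambda1|, |lambda2|, 1)``
    of zero yields the DEGENERATE label (the zero-eigenvalue boundary is
    flagged rather than analyzed).
    """
    A = build_system_matrix(rates)
    lam1, lam2, _, _ = _eigenpairs(A)
    tol = DEGENERATE_RTOL * max(abs(lam1), abs(lam2), 1.0)
    if abs(lam1) < tol or abs(lam2) < tol:
        label = StabilityLabel.DEGENERATE
    elif lam2 > 0:
        label = StabilityLabel.UNSTABLE_NODE
    elif lam1 < 0:
        label = StabilityLabel.STABLE_NODE
    else:
        label = StabilityLabel.SADDLE
    return StabilityClass(
        label=label,
        lambda1=lam1,
        lambda2=lam2,
        ratio_condition=saddle_ratio_condition(rates),
    )


def solve_trajectory(
    rates: RateConstants, x0: TumorState, t_grid: Sequence[float]
) -> np.ndarray:
    """Evaluate the closed-form solution x(t) = c1 e^{l1 t} v1 + c2 e^{l2 t} v2.

    Parameters
    ----------
    t_grid
        Non-negative, strictly increasing times.

    Returns
    -------
    ndarray of shape (len(t_grid), 2) with columns (x1, x2).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValidationError("time grid must be non-empty")
    if t[0] < 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValidationError("time grid must be non-negative and increasing")
    eig = eigenstructure(build_system_matrix(rates), x0)
    mode1 = np.outer(eig.c1 * np.exp(eig.lambda1 * t), eig.v1)
    mode2 = np.outer(eig.c2 * np.exp(eig.lambda2 * t), eig.v2)
    return mode1 + mode2


def trajectory_frame(rates: RateConstants, x0: TumorState, t_grid: Sequence[float]):
    """Trajectory as a DataFrame with columns t, x1, x2, N (CSV-ready)."""
    import pandas as pd

    xs = solve_trajectory(rates, x0, t_grid)
    return pd.DataFrame(
        {
            "t": np.asarray(t_grid, dtype=float),
            "x1": xs[:, 0],
            "x2": xs[:, 1],
            "N": xs.sum(axis=1),
        }
    )
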