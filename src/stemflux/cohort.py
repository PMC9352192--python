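"""Virtual patient cohorts and Kaplan-Meier progression-free curves.

Patients differ in their basal rates of cell birth, death, and state
transition (b_S, b_R, delta = delta_S = delta_R, kappa, k_RS) and in the
fraction of resistant cells present when the tumor is detected; each is an
independent uniform random variable.  Tumor size at detection and the
pharmacodynamic constants (efficacies, EC50s, saturation rates) are fixed
across patients — they are properties of clinical practice and of the drug.

For each patient and each fixed dose the exact time to progression is
computed from that patient's rate constants; a cohort's Kaplan-Meier curve
is the fraction of its patients still progression-free at each time, and an
ensemble of cohorts is summarized by the pointwise mean and standard
deviation of those curves.

RNG discipline: one master seed; the substream for patient p of cohort c is
derived as ``SeedSequence(seed, spawn_key=(c, p))``, so enlarging the cohort
or adding cohorts never reshuffles previously drawn patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ValidationError
from .pharmacodynamics import PharmacodynamicSet, validate_dose
from .progression import ttp_exact_batch

__all__ = [
    "PatientDistributions",
    "CohortConfig",
    "CohortResult",
    "KMEnsemble",
    "sample_patient",
    "simulate_cohorts",
    "km_curve",
    "aggregate_cohorts",
]

#: resampling cap for draws violating the joint constraint b_S > b_R
RESAMPLE_CAP = 100

#: parameters sampled per patient, in draw order
PATIENT_PARAMS = ("b_S", "b_R", "delta", "kappa", "k_RS", "resistant_fraction")


@dataclass(frozen=True)
class PatientDistributions:
    """Independent uniform ranges for the patient-level parameters.

    Each field is a ``(low, high)`` pair; ``low == high`` gives a point
    mass.  Rates must stay strictly positive over their ranges and the
    resistant fraction within [0, 1).
    """

    b_S: tuple[float, float]
    b_R: tuple[float, float]
    delta: tuple[float, float]
    kappa: tuple[float, float]
    k_RS: tuple[float, float]
    resistant_fraction: tuple[float, float]

    def __post_init__(self) -> None:
        for name in PATIENT_PARAMS:
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValidationError(f"range for {name} has lower > upper")
            if name == "resistant_fraction":
                if lo < 0 or hi >= 1:
                    raise ValidationError(
                        "resistant-fraction range must lie within [0, 1)"
                    )
            elif lo <= 0:
                raise ValidationError(
                    f"range for {name} must be strictly positive"
                )
        if self.b_S[1] <= self.b_R[0]:
            raise ValidationError(
                "b_S range lies entirely at or below b_R range; the fitness "
                "cost constraint b_S > b_R can never hold"
            )

    @classmethod
    def from_baseline(
        cls,
        baseline: dict,
        rel_width: float = 0.2,
        resistant_fraction: tuple[float, float] = (0.001, 0.05),
    ) -> "PatientDistributions":
        """Uniform ranges of +/- ``rel_width`` around baseline rates.

        The default width (20 %) keeps most sampled patients in the saddle
        regime at intermediate doses, so cohort KM curves remain
        informative about progression rather than immediate growth.
        """

        def around(key: str) -> tuple[float, float]:
            v = baseline[key]
            return (v * (1.0 - rel_width), v * (1.0 + rel_width))

        return cls(
            b_S=around("b_S"),
            b_R=around("b_R"),
            delta=around("delta_S"),
            kappa=around("kappa"),
            k_RS=around("k_RS"),
            resistant_fraction=resistant_fraction,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Size, dose grid, evaluation grid and seed of a cohort simulation."""

    n_p: int
    n_c: int
    doses: np.ndarray
    t_grid: np.ndarray
    horizon: float
    seed: int
    N0: float = 1.0e9

    def __post_init__(self) -> None:
        if self.n_p < 1 or self.n_c < 1:
            raise ValidationError("n_p and n_c must both be >= 1")
        doses = np.atleast_1d(np.asarray(self.doses, dtype=float))
        validate_dose(doses)
        t = np.atleast_1d(np.asarray(self.t_grid, dtype=float))
        if t[0] < 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise ValidationError("time grid must be increasing from >= 0")
        if self.horizon <= 0:
            raise ValidationError("horizon must be positive")
        if self.N0 <= 0:
            raise ValidationError("N0 must be positive")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "t_grid", t)


def sample_patient(dists: PatientDistributions, rng: np.random.Generator) -> dict:
    """Draw one patient's parameter bundle.

    Draws each parameter independently and uniformly; draws violating the
    joint constraint b_S > b_R are rejected and redrawn, up to
    ``RESAMPLE_CAP`` attempts.
    """
    for _ in range(RESAMPLE_CAP):
        draw = {
            name: float(rng.uniform(*getattr(dists, name)))
            for name in PATIENT_PARAMS
        }
        if draw["b_S"] > draw["b_R"]:
            return draw
    raise ValidationError(
        f"failed to satisfy b_S > b_R within {RESAMPLE_CAP} resampling "
        "attempts; check the distribution ranges"
    )


@dataclass(frozen=True)
class CohortResult:
    """Per-cohort, per-patient, per-dose exact TTP with censoring flags."""

    t_P: np.ndarray        # shape (n_c, n_p, n_doses)
    censored: np.ndarray   # same shape, bool
    doses: np.ndarray
    patients: dict[str, np.ndarray]  # sampled params, each (n_c, n_p)
    config: CohortConfig

    def to_frame(self):
        """Long-format table: cohort, patient, dose, t_P, censored."""
        import pandas as pd

        n_c, n_p, n_m = self.t_P.shape
        c, p, m = np.meshgrid(
            np.arange(n_c), np.arange(n_p), self.doses, indexing="ij"
        )
        return pd.DataFrame(
            {
                "cohort": c.ravel(),
                "patient": p.ravel(),
                "m": m.ravel(),
                "t_P": self.t_P.ravel(),
                "censored": self.censored.ravel(),
            }
        )


def simulate_cohorts(
    cfg: CohortConfig,
    dists: PatientDistributions,
    pd_set: PharmacodynamicSet,
) -> CohortResult:
    """Sample all patients and compute each one's exact TTP at every dose.

    Patient-level draws replace the basal rates (the logistic offsets and
    the dose-independent rates); the drug's efficacy, saturation and EC50
    constants come unchanged from ``pd_set``.  The initial state splits the
    fixed detection size ``cfg.N0`` by each patient's resistant fraction.
    """
    n_c, n_p = cfg.n_c, cfg.n_p
    params = {name: np.empty((n_c, n_p)) for name in PATIENT_PARAMS}
    root = np.random.SeedSequence(cfg.seed)
    for c in range(n_c):
        for p in range(n_p):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(c, p))
            )
            draw = sample_patient(dists, rng)
            for name in PATIENT_PARAMS:
                params[name][c, p] = draw[name]

    m = cfg.doses[np.newaxis, np.newaxis, :]          # (1, 1, n_m)
    ds, dr, ks = pd_set.ds_curve, pd_set.dr_curve, pd_set.ksr_curve
    delta = params["delta"][..., np.newaxis]
    rates = {
        "b_S": params["b_S"][..., np.newaxis],
        "b_R": params["b_R"][..., np.newaxis],
        # patients vary the basal (offset) rates; drug increments are fixed
        "d_S": delta + ds.E / (1.0 + np.exp(-ds.r * (m - ds.P))),
        "d_R": delta + dr.E / (1.0 + np.exp(-dr.r * (m - dr.P))),
        "k_SR": params["kappa"][..., np.newaxis]
        + ks.E / (1.0 + np.exp(-ks.r * (m - ks.P))),
        "k_RS": params["k_RS"][..., np.newaxis],
    }
    f = params["resistant_fraction"][..., np.newaxis]
    t_P, censored = ttp_exact_batch(
        rates, x1=cfg.N0 * (1.0 - f), x2=cfg.N0 * f, horizon=cfg.horizon
    )
    return CohortResult(
        t_P=t_P, censored=censored, doses=cfg.doses,
        patients=params, config=cfg,
    )


def km_curve(
    tp_values: np.ndarray,
    t_grid: np.ndarray,
    censored: np.ndarray | None = None,
) -> np.ndarray:
    """Progression-free fraction of one cohort at each evaluation time.

    fraction(t) = #{patients with t_P > t} / n_p, with patients censored at
    the horizon counted as progression-free throughout (the evaluation grid
    is expected not to exceed the horizon).
    """
    tp = np.atleast_1d(np.asarray(tp_values, dtype=float))
    if tp.size == 0:
        raise ValidationError("patient list must be non-empty")
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValidationError("time grid must be strictly increasing")
    if censored is None:
        censored = np.zeros(tp.shape, dtype=bool)
    free = censored[:, np.newaxis] | (tp[:, np.newaxis] > t[np.newaxis, :])
    return free.mean(axis=0)


@dataclass(frozen=True)
class KMEnsemble:
    """Mean and spread of cohort-level Kaplan-Meier curves per dose."""

    doses: np.ndarray
    t_grid: np.ndarray
    mean: np.ndarray  # shape (n_doses, n_t)
    sd: np.ndarray    # shape (n_doses, n_t)

    def to_frame(self):
        import pandas as pd

        mm, tt = np.meshgrid(self.doses, self.t_grid, indexing="ij")
        return pd.DataFrame(
            {
                "m": mm.ravel(),
                "t": tt.ravel(),
                "mean_fraction": self.mean.ravel(),
                "sd": self.sd.ravel(),
            }
        )


def aggregate_cohorts(
    result: CohortResult, t_grid: np.ndarray | None = None
) -> KMEnsemble:
    """Pointwise mean and standard deviation of per-cohort KM curves.

    The spread across cohorts (population SD, zero for a single cohort)
    quantifies trial-to-trial variability; no within-cohort variance
    estimate is attached.
    """
    t = np.asarray(t_grid if t_grid is not None else result.config.t_grid,
                   dtype=float)
    n_c, n_p, n_m = result.t_P.shape
    curves = np.empty((n_c, n_m, t.size))
    for c in range(n_c):
        for j in range(n_m):
            curves[c, j] = km_curve(
                result.t_P[c, :, j], t, censored=result.censored[c, :, j]
            )
    return KMEnsemble(
        doses=result.doses,
        t_grid=t,
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=0),
    )
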