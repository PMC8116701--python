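"""Two-compartment IV-bolus structural model and covariate/random-effect map.

The population model describes iohexol plasma disposition in dogs after a
single intravenous bolus.  Individual parameters arise from typical values
(fixed effects), a covariate model on clearance (CKD status and centered
serum creatinine, both acting multiplicatively on the log scale), and
log-normal inter-individual random effects:

    Cl_i = theta_cl * exp(beta_ckd*ckd_i + beta_creat*(creat_i - c0) + eta_cl,i)
    V1_i = theta_v1 * exp(eta_v1,i)
    V2_i = theta_v2 * exp(eta_v2,i)
    Q_i  = theta_q                      (no random effect)

All clearances and volumes are per kilogram of body weight and the dose is
given per kilogram, so body weight cancels throughout and is carried only
as metadata.  Residual error is proportional: sd(Y|f) = sigma_prop * f.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "PopulationModel",
    "DogCovariates",
    "IndividualParams",
    "RandomEffects",
    "individual_from_effects",
    "concentration",
    "residual_sd",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """A model parameter or input violates its domain constraint."""


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate coefficients, random-effect SDs and residual error.

    Units: clearances L/min/kg, volumes L/kg, ``beta_creat`` dl/mg,
    ``creat_center`` mg/dl; random-effect SDs and ``sigma_prop`` are
    dimensionless (log scale / proportional).
    """

    theta_cl: float = 0.00212
    theta_v1: float = 0.163
    theta_v2: float = 0.058
    theta_q: float = 0.0034
    beta_ckd: float = -0.379
    beta_creat: float = -0.421
    creat_center: float = 1.47
    omega_cl: float = 0.208
    omega_v1: float = 0.248
    omega_v2: float = 0.199
    sigma_prop: float = 0.0617

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_v1", "theta_v2",
                     "omega_cl", "omega_v1", "omega_v2", "sigma_prop"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")
        # q = 0 is the one-compartment limit, allowed; negative is not.
        if not np.isfinite(self.theta_q) or self.theta_q < 0:
            raise InvalidParameterError(f"theta_q must be non-negative, got {self.theta_q!r}")
        for name in ("beta_ckd", "beta_creat", "creat_center"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    @property
    def omega(self) -> np.ndarray:
        """Diagonal of the random-effect SD vector (cl, v1, v2)."""
        return np.array([self.omega_cl, self.omega_v1, self.omega_v2])

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class DogCovariates:
    """Covariate record for one dog: CKD status and serum creatinine.

    ``weight`` is informational only (the model is per-kg throughout).
    """

    ckd: int
    creatinine: float
    weight: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.ckd not in (0, 1):
            raise InvalidParameterError(f"ckd must be 0 or 1, got {self.ckd!r}")
        if not np.isfinite(self.creatinine) or self.creatinine <= 0:
            raise InvalidParameterError(
                f"creatinine must be strictly positive, got {self.creatinine!r}")


@dataclass(frozen=True)
class IndividualParams:
    """Individual PK parameter vector (Cl, V1, V2, Q), all per kg."""

    cl: float
    v1: float
    v2: float
    q: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "v2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.q) or self.q < 0:
            raise InvalidParameterError(f"q must be non-negative, got {self.q!r}")


@dataclass(frozen=True)
class RandomEffects:
    """Log-scale individual deviations (eta_cl, eta_v1, eta_v2)."""

    eta_cl: float = 0.0
    eta_v1: float = 0.0
    eta_v2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eta_cl", "eta_v1", "eta_v2"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_cl, self.eta_v1, self.eta_v2])


def log_cl_fixed(pop: PopulationModel, cov: DogCovariates) -> float:
    """Covariate-predicted log clearance before the random effect."""
    return (np.log(pop.theta_cl)
            + pop.beta_ckd * cov.ckd
            + pop.beta_creat * (cov.creatinine - pop.creat_center))


def individual_from_effects(pop: PopulationModel, cov: DogCovariates,
                            eta: RandomEffects) -> IndividualParams:
    """Map (theta, covariates, eta) to the individual parameter vector phi."""
    cl = np.exp(log_cl_fixed(pop, cov) + eta.eta_cl)
    v1 = pop.theta_v1 * np.exp(eta.eta_v1)
    v2 = pop.theta_v2 * np.exp(eta.eta_v2)
    for name, v in (("cl", cl), ("v1", v1), ("v2", v2)):
        if not np.isfinite(v) or v <= 0:
            raise InvalidParameterError(f"individual {name} is not finite/positive: {v!r}")
    return IndividualParams(cl=float(cl), v1=float(v1), v2=float(v2), q=pop.theta_q)


def _conc2(cl, v1, v2, q, dose_per_kg, t):
    """Vectorised two-compartment bolus concentration, broadcasting over all args.

    Returns mg/L == ug/ml for dose in mg/kg and volumes in L/kg.  The
    repeated-root case alpha ~= beta is evaluated by its analytic limit.
    """
    cl, v1, v2, q, t = np.broadcast_arrays(
        np.asarray(cl, float), np.asarray(v1, float), np.asarray(v2, float),
        np.asarray(q, float), np.asarray(t, float))
    k10 = cl / v1
    k12 = q / v1
    k21 = np.divide(q, v2, out=np.zeros_like(q), where=v2 > 0)
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    c0 = np.asarray(dose_per_kg, float) / v1

    sep = disc > 1e-12 * s
    denom = np.where(sep, alpha - beta, 1.0)
    a_coef = (alpha - k21) / denom
    b_coef = (k21 - beta) / denom
    biexp = a_coef * np.exp(-alpha * t) + b_coef * np.exp(-beta * t)
    # alpha -> beta limit: e^(-alpha t) * (1 + (k21 - alpha) t)
    repeated = np.exp(-alpha * t) * (1.0 + (k21 - alpha) * t)
    return c0 * np.where(sep, biexp, repeated)


def concentration(phi: IndividualParams, dose_per_kg: float, t):
    """Plasma concentration (ug/ml) at time(s) ``t`` minutes after an IV bolus.

    Closed-form bi-exponential solution of the two-compartment mass-balance
    system; ``t`` may be a scalar or an array (minutes, >= 0).
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise InvalidParameterError("times must be non-negative")
    if dose_per_kg <= 0:
        raise InvalidParameterError("dose_per_kg must be strictly positive")
    out = _conc2(phi.cl, phi.v1, phi.v2, phi.q, dose_per_kg, t)
    return float(out) if out.ndim == 0 else out


def residual_sd(pop: PopulationModel, f_value):
    """Proportional residual SD g = sigma_prop * f (ug/ml)."""
    f_value = np.asarray(f_value, float)
    if np.any(f_value < 0):
        raise InvalidParameterError("model prediction f must be non-negative")
    out = pop.sigma_prop * f_value
    return float(out) if out.ndim == 0 else out
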