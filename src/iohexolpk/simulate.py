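"""Monte-Carlo simulation of iohexol profiles and synthetic study cohorts.

Two generators live here.  ``simulate_profiles`` is the design-evaluation
engine: for a single covariate combination it draws replicate random
effects eta* ~ N(0, Omega), builds individual parameters, and produces
noisy concentrations Y*_t = f(t; phi*) * (1 + b*eps) with eps ~ N(0,1)
i.i.d. across times.  ``generate_cohort`` emulates a whole study cohort
(healthy and CKD dogs with covariates spanning the observed clinical
ranges) and returns a long-format dataset.  ``vpc_percentiles`` summarises
repeated cohort simulations into visual-predictive-check bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (DogCovariates, InvalidParameterError, PopulationModel,
                    _conc2, log_cl_fixed)

__all__ = ["SimulationConfig", "SimulatedProfiles", "simulate_profiles",
           "generate_cohort", "vpc_percentiles", "CANDIDATE_GRID",
           "STUDY_TIMES", "STUDY_DOSE"]

#: candidate sampling grid for design optimisation (min)
CANDIDATE_GRID = (30, 60, 90, 120, 150, 180)
#: sampling schedule of the study cohort (min)
STUDY_TIMES = (5, 15, 60, 90, 180)
#: nominal IV bolus dose (mg/kg)
STUDY_DOSE = 64.7


@dataclass(frozen=True)
class SimulationConfig:
    """Replicate count, time grid, dose and seed for profile simulation."""

    n_replicates: int = 5000
    times: tuple = CANDIDATE_GRID
    dose_per_kg: float = STUDY_DOSE
    seed: int = 0
    truncate_nonpositive: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        t = np.asarray(self.times, float)
        if t.size == 0:
            raise InvalidParameterError("time grid must not be empty")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing and > 0")
        if self.dose_per_kg <= 0:
            raise InvalidParameterError("dose_per_kg must be > 0")


@dataclass
class SimulatedProfiles:
    """Replicate draws from the population model for one covariate set.

    ``eta`` (n, 3) are the true random effects exactly as drawn, ``cl_true``
    the corresponding true clearances, and ``concentrations`` (n, k) the
    noisy observations on ``times``.
    """

    times: np.ndarray
    eta: np.ndarray
    cl_true: np.ndarray
    concentrations: np.ndarray
    dose_per_kg: float
    n_nonpositive: int = 0

    def __len__(self) -> int:
        return self.eta.shape[0]


def simulate_profiles(pop: PopulationModel, cov: DogCovariates,
                      cfg: SimulationConfig) -> SimulatedProfiles:
    """Draw replicate (eta*, Y*) pairs for one dog's covariates.

    Identical seeds give bitwise-identical output.  Non-positive simulated
    concentrations (probability ~Phi(-1/b), negligible at b ~ 6%) are kept
    unless ``cfg.truncate_nonpositive`` resamples their noise.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_replicates
    times = np.asarray(cfg.times, float)
    om = pop.omega
    if np.any(om <= 0):
        raise InvalidParameterError("random-effect SDs must be strictly positive")
    eta = rng.standard_normal((n, 3)) * om
    lc0 = log_cl_fixed(pop, cov)
    cl = np.exp(lc0 + eta[:, 0])
    v1 = pop.theta_v1 * np.exp(eta[:, 1])
    v2 = pop.theta_v2 * np.exp(eta[:, 2])
    f = _conc2(cl[:, None], v1[:, None], v2[:, None], pop.theta_q,
               cfg.dose_per_kg, times[None, :])
    eps = rng.standard_normal((n, times.size))
    y = f * (1.0 + pop.sigma_prop * eps)
    n_nonpos = int((y <= 0).sum())
    if cfg.truncate_nonpositive and n_nonpos:
        bad = y <= 0
        while bad.any():
            y[bad] = f[bad] * (1.0 + pop.sigma_prop * rng.standard_normal(int(bad.sum())))
            bad = y <= 0
        n_nonpos = 0
    return SimulatedProfiles(times=times, eta=eta, cl_true=cl,
                             concentrations=y, dose_per_kg=cfg.dose_per_kg,
                             n_nonpositive=n_nonpos)


def _draw_covariates(rng: np.random.Generator, n_healthy: int, n_ckd: int
                     ) -> pd.DataFrame:
    """Synthetic covariate table spanning the clinical ranges of the cohort.

    The within-stratum creatinine distributions are log-normal stand-ins
    (healthy centred near 1.0 mg/dl, CKD near 1.8 mg/dl with a heavy upper
    tail) calibrated only to span roughly 0.67-14.4 mg/dl pooled; they are
    a fixture, not an estimate from data.  Weight is uniform on [3.9, 46] kg.
    """
    ckd = np.r_[np.zeros(n_healthy, int), np.ones(n_ckd, int)]
    creat = np.r_[np.exp(rng.normal(np.log(1.0), 0.18, n_healthy)),
                  np.exp(rng.normal(np.log(1.8), 0.65, n_ckd))]
    creat = np.clip(creat, 0.5, 15.0)
    weight = rng.uniform(3.9, 46.0, n_healthy + n_ckd)
    return pd.DataFrame({
        "ID": [f"dog{i + 1:03d}" for i in range(n_healthy + n_ckd)],
        "CKD": ckd, "CREAT": np.round(creat, 3), "WT": np.round(weight, 1)})


def generate_cohort(pop: PopulationModel, n_healthy: int = 29, n_ckd: int = 20,
                    design_times=STUDY_TIMES, dose_per_kg: float = STUDY_DOSE,
                    seed: int = 0):
    """Simulate a full study cohort; returns (long-format DataFrame, covariates).

    Each dog gets one profile at ``design_times``; the long table follows
    the ``ID,TIME,DV,AMT,CKD,CREAT,WT`` dialect with a dose row at TIME=0.
    """
    if n_healthy < 0 or n_ckd < 0:
        raise InvalidParameterError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    covs = _draw_covariates(rng, n_healthy, n_ckd)
    times = np.asarray(design_times, float)
    rows = []
    for _, row in covs.iterrows():
        cov = DogCovariates(ckd=int(row.CKD), creatinine=float(row.CREAT),
                            weight=float(row.WT), id=str(row.ID))
        eta = rng.standard_normal(3) * pop.omega
        cl = np.exp(log_cl_fixed(pop, cov) + eta[0])
        v1 = pop.theta_v1 * np.exp(eta[1])
        v2 = pop.theta_v2 * np.exp(eta[2])
        f = _conc2(cl, v1, v2, pop.theta_q, dose_per_kg, times)
        y = f * (1.0 + pop.sigma_prop * rng.standard_normal(times.size))
        rows.append({"ID": row.ID, "TIME": 0.0, "DV": np.nan,
                     "AMT": dose_per_kg, "CKD": row.CKD, "CREAT": row.CREAT,
                     "WT": row.WT})
        for t, c in zip(times, y):
            rows.append({"ID": row.ID, "TIME": float(t), "DV": float(c),
                         "AMT": np.nan, "CKD": row.CKD, "CREAT": row.CREAT,
                         "WT": row.WT})
    return pd.DataFrame(rows), covs


def vpc_percentiles(simulated, observed: pd.DataFrame | None = None,
                    probs=(10, 50, 90), inner=(5, 95)) -> pd.DataFrame:
    """Visual-predictive-check bands from repeated cohort simulations.

    ``simulated`` is a sequence of long-format cohort DataFrames all sharing
    one observation time grid.  For each time and each percentile in
    ``probs`` the function returns the Monte-Carlo median of that theoretical
    percentile and its ``inner`` prediction interval, plus (when ``observed``
    is given) the matching empirical percentile of the observed data.
    """
    if len(simulated) < 1:
        raise ValueError("need at least one simulated cohort")
    grids = [np.unique(df.loc[df["DV"].notna(), "TIME"]) for df in simulated]
    for g in grids[1:]:
        if not np.array_equal(g, grids[0]):
            raise ValueError("simulated cohorts must share one time grid")
    times = grids[0]
    if observed is not None and len(observed):
        obs_times = np.unique(observed.loc[observed["DV"].notna(), "TIME"])
        if not np.array_equal(obs_times, times):
            raise ValueError("observed time grid does not match simulations")
    records = []
    for t in times:
        per_cohort = np.array([
            np.percentile(df.loc[(df["TIME"] == t) & df["DV"].notna(), "DV"], probs)
            for df in simulated])                     # (n_cohorts, n_probs)
        for j, p in enumerate(probs):
            rec = {"TIME": t, "percentile": p,
                   "theoretical": float(np.median(per_cohort[:, j])),
                   "pi_low": float(np.percentile(per_cohort[:, j], inner[0])),
                   "pi_high": float(np.percentile(per_cohort[:, j], inner[1]))}
            if observed is not None and len(observed):
                obs = observed.loc[(observed["TIME"] == t) & observed["DV"].notna(), "DV"]
                rec["observed"] = float(np.percentile(obs, p))
            records.append(rec)
    return pd.DataFrame(records)
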