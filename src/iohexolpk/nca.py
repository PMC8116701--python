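"""Non-compartmental clearance and Bland-Altman agreement statistics.

The comparator method estimates clearance model-free as Dose/AUC (per kg,
so body weight cancels): AUC from 0 to the last sample by the linear-up /
log-down trapezoid rule, the pre-first-sample segment by log-linear
back-extrapolation of C(0) from the first two points (standard bolus NCA),
and the tail beyond the last sample by C_last/lambda_z with the terminal
slope lambda_z from a log-linear regression on the last points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgreementSummary", "nca_clearance", "bland_altman"]


class ExtrapolationError(RuntimeError):
    """Terminal phase is not declining; AUC cannot be extrapolated."""


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman bias and 95% limits of agreement for paired methods."""

    bias: float
    loa_low: float
    loa_high: float
    n_pairs: int


def _auc_linup_logdown(t: np.ndarray, c: np.ndarray) -> float:
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    lin = 0.5 * (c0 + c1) * dt
    down = (c1 < c0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c0 - c1) / np.log(c0 / c1) * dt
    return float(np.sum(np.where(down, log_seg, lin)))


def nca_clearance(times, concentrations, dose_per_kg: float,
                  n_lambda_z: int = 3, back_extrapolate: bool = True) -> float:
    """Non-compartmental clearance Dose/AUC_0-inf in L/min/kg.

    Parameters
    ----------
    times, concentrations
        Sampling times (min) and plasma concentrations (ug/ml); at least
        three positive observations.  Input order is irrelevant (sorted).
    n_lambda_z
        Number of terminal points in the log-linear lambda_z regression.
    back_extrapolate
        Extend the AUC to t=0 using C(0) log-back-extrapolated from the
        first two samples (disable to start the AUC at the first sample).
    """
    t = np.asarray(times, float)
    c = np.asarray(concentrations, float)
    if t.size != c.size:
        raise ValueError("times and concentrations must have equal length")
    if t.size < 3:
        raise ValueError("NCA needs at least 3 observations")
    if np.any(c <= 0) or np.any(t < 0):
        raise ValueError("concentrations must be positive and times non-negative")
    if dose_per_kg <= 0:
        raise ValueError("dose_per_kg must be positive")
    order = np.argsort(t)
    t, c = t[order], c[order]
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate sampling times")

    if n_lambda_z < 2 or n_lambda_z > t.size:
        raise ValueError("n_lambda_z must be in [2, n_observations]")
    tt, cc = t[-n_lambda_z:], np.log(c[-n_lambda_z:])
    slope = np.polyfit(tt, cc, 1)[0]
    lambda_z = -slope
    if lambda_z <= 0:
        raise ExtrapolationError(
            f"terminal phase not declining (lambda_z = {lambda_z:.3g}/min)")

    auc = _auc_linup_logdown(t, c)
    if back_extrapolate and t[0] > 0:
        # log-linear through the first two (declining) points back to t=0
        if c[1] < c[0]:
            k0 = np.log(c[0] / c[1]) / (t[1] - t[0])
            c_zero = c[0] * np.exp(k0 * t[0])
            auc += (c_zero - c[0]) / np.log(c_zero / c[0]) * t[0]
        else:
            auc += c[0] * t[0]
    auc_inf = auc + c[-1] / lambda_z
    return float(dose_per_kg / auc_inf)


def bland_altman(a, b) -> AgreementSummary:
    """Bland-Altman comparison of two paired clearance series (d = a - b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D paired vectors")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementSummary(bias=bias, loa_low=bias - 1.96 * sd,
                            loa_high=bias + 1.96 * sd, n_pairs=int(a.size))


def bland_altman_plot(a, b, path=None, labels=("method A", "method B")):
    """Scatter of differences vs means with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    s = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=18, alpha=0.7)
    ax.axhline(s.bias, color="tab:blue", label=f"bias {s.bias:.3g}")
    for y in (s.loa_low, s.loa_high):
        ax.axhline(y, color="tab:red", ls="--")
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]}")
    ax.set_ylabel(f"{labels[0]} - {labels[1]}")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
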