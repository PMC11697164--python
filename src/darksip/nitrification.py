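"""Nitrification rates from 15N-NOx incubation time series.

A tracer experiment amends seawater with 15N-labeled ammonium or urea and
follows the appearance of 15N in the NOx (nitrate + nitrite) pool over time.
The rate of total N oxidation is the ordinary-least-squares slope of the
excess 15N-NOx concentration against time, divided by the 15N atom fraction
of the amended substrate pool (tracer dilution correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AIR_N2_RATIO",
    "NitrificationResult",
    "RateComparison",
    "delta_to_atom_fraction",
    "excess_15N_concentration",
    "fit_rate",
    "fit_rate_per_replicate",
    "compare_rates",
]

#: 15N/14N isotope ratio of the atmospheric N2 standard.
AIR_N2_RATIO = 0.0036765


def delta_to_atom_fraction(delta_permil, r_standard: float = AIR_N2_RATIO):
    """Convert delta-15N (per mil vs air-N2) to the 15N atom fraction.

    ``R = (delta/1000 + 1) * R_std`` and ``x = R / (1 + R)``.
    """
    d = np.asarray(delta_permil, dtype=float)
    if np.any(d <= -1000.0):
        raise ValueError("delta must be > -1000 permil")
    r = (d / 1000.0 + 1.0) * r_standard
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def excess_15N_concentration(x_t, x_0, nox_uM):
    """Excess 15N in the NOx pool, nmol 15N per liter.

    ``excess = (x_t - x_0) * [NOx in umol/L] * 1000``. Negative values are
    allowed (measurement noise).
    """
    nox = np.asarray(nox_uM, dtype=float)
    if np.any(nox <= 0):
        raise ValueError("NOx concentration must be positive")
    out = (np.asarray(x_t, dtype=float) - np.asarray(x_0, dtype=float)) * nox * 1000.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NitrificationResult:
    """Rate of total N oxidation from one fitted incubation."""

    rate: float  # nmol N L-1 d-1
    stderr: float  # same units
    p_slope: float  # one-sided p-value for slope > 0
    detected: bool
    n_points: int


def _excess_series(series: pd.DataFrame, r_standard: float) -> tuple[np.ndarray, np.ndarray]:
    t_h = series["timepoint_h"].to_numpy(dtype=float)
    delta = series["delta15N_NOx_permil"].to_numpy(dtype=float)
    nox = series["nox_uM"].to_numpy(dtype=float)
    if np.isnan(nox).any():
        # missing timepoint-specific NOx: fall back to the series mean
        nox = np.where(np.isnan(nox), np.nanmean(nox), nox)
    x = delta_to_atom_fraction(delta, r_standard)
    t0 = t_h.min()
    x0 = float(np.mean(x[t_h == t0]))
    excess = excess_15N_concentration(x, x0, nox)
    return t_h / 24.0, excess


def fit_rate(
    series: pd.DataFrame,
    x_sub: float,
    r_standard: float = AIR_N2_RATIO,
    alpha: float = 0.05,
) -> NitrificationResult:
    """OLS rate of total N oxidation from a pooled 15N-NOx time series.

    All replicates in ``series`` (columns ``timepoint_h``,
    ``delta15N_NOx_permil``, ``nox_uM``) are pooled into one regression of
    excess 15N-NOx against time. The slope (nmol 15N L^-1 d^-1) is divided by
    the substrate 15N atom fraction ``x_sub`` to convert tracer production to
    total N oxidized. Detection requires a positive slope with one-sided
    p < ``alpha``; a negative fitted slope is reported as rate 0, undetected.
    """
    if not (0.0 < x_sub <= 1.0):
        raise ValueError("x_sub must be in (0, 1]")
    if x_sub <= AIR_N2_RATIO:
        raise ValueError("substrate atom fraction must exceed natural abundance")
    t_d, excess = _excess_series(series, r_standard)
    if len(t_d) < 3:
        raise ValueError("need at least 3 (time, excess) points")
    if np.ptp(t_d) == 0:
        raise ValueError("zero time variance; cannot fit a rate")
    fit = stats.linregress(t_d, excess)
    slope, stderr = float(fit.slope), float(fit.stderr)
    if stderr == 0.0:
        # perfectly collinear points: slope is exact
        p_one = 0.0 if slope > 0 else 1.0
    else:
        p_two = float(fit.pvalue)
        p_one = p_two / 2.0 if slope > 0 else 1.0 - p_two / 2.0
    detected = (slope > 0) and (p_one < alpha)
    rate = max(slope, 0.0) / x_sub
    return NitrificationResult(
        rate=rate,
        stderr=stderr / x_sub,
        p_slope=p_one,
        detected=detected,
        n_points=int(len(t_d)),
    )


def fit_rate_per_replicate(
    series: pd.DataFrame,
    x_sub: float,
    r_standard: float = AIR_N2_RATIO,
    alpha: float = 0.05,
) -> dict[str, NitrificationResult]:
    """One fit per ``replicate_id``, for replicate-level rate comparisons."""
    return {
        str(rep): fit_rate(grp, x_sub, r_standard, alpha)
        for rep, grp in series.groupby("replicate_id", sort=True)
    }


@dataclass(frozen=True)
class RateComparison:
    """Welch two-sample t comparison of replicate-level rates."""

    statistic: float
    pvalue: float
    indistinguishable: bool  # True when p > alpha


def compare_rates(
    rates_a: Iterable[float], rates_b: Iterable[float], alpha: float = 0.05
) -> RateComparison:
    """Two-sided Welch t-test on replicate-level rate estimates."""
    a = np.asarray(list(rates_a), dtype=float)
    b = np.asarray(list(rates_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicate rates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("both groups constant and equal; t = 0, p = 1", stacklevel=2)
            return RateComparison(statistic=0.0, pvalue=1.0, indistinguishable=True)
        warnings.warn("both groups constant; Welch test degenerate", stacklevel=2)
        return RateComparison(statistic=np.inf, pvalue=0.0, indistinguishable=False)
    res = stats.ttest_ind(a, b, equal_var=False)
    return RateComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        indistinguishable=bool(res.pvalue > alpha),
    )
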