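"""Oscillation-period estimation from the autocorrelation function.

Some ATP-regulation mutants (e.g. cells lacking the Bas1 transcription
factor) show slow, unsynchronized oscillations of intracellular ATP with a
period of roughly half an hour.  The apparent period is read from the sample
autocorrelation function (ACF) of the per-cell ratio trace: the first
positive-lag local maximum of the correlation coefficient that is positive
and lies outside the 95% confidence band around zero (the lag-0 peak being
the trivial first peak).  Its lag times the frame interval is the period.

Because the peak is searched over every candidate lag rather than chosen by
eye, the significance threshold is Šidák-corrected for the number of lags
scanned; otherwise white noise would yield a spurious "significant" peak in
a large fraction of traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from statsmodels.tsa.stattools import acf as sm_acf

from .traces import RatioTrace

__all__ = ["AcfResult", "PeriodEstimate", "autocorrelation", "estimate_period"]


@dataclass(frozen=True)
class AcfResult:
    """Sample ACF with its no-correlation 95% band.

    ``ci_halfwidth`` is the per-lag band 1.96/sqrt(T) under the white-noise
    null; ``n_effective`` the number of frames the ACF was computed from.
    """

    lags: np.ndarray
    coefficients: np.ndarray
    ci_halfwidth: float
    n_effective: int
    zero_variance: bool = False


@dataclass(frozen=True)
class PeriodEstimate:
    period_min: float | None
    peak_lag: int | None
    peak_coefficient: float | None
    significant: bool
    threshold: float


def autocorrelation(
    trace: RatioTrace | np.ndarray, max_lag: int, detrend: bool = False
) -> AcfResult:
    """Sample autocorrelation of the (optionally linearly detrended) trace."""
    x = trace.ratio if isinstance(trace, RatioTrace) else np.asarray(trace, dtype=float)
    T = x.size
    if not 1 <= max_lag < T:
        raise ValueError(f"max_lag must satisfy 1 <= max_lag < {T}, got {max_lag}")
    if detrend:
        x = signal.detrend(x, type="linear")
    lags = np.arange(max_lag + 1)
    ci = 1.96 / np.sqrt(T)
    if np.var(x) == 0:
        coeffs = np.full(max_lag + 1, np.nan)
        coeffs[0] = 1.0
        return AcfResult(lags=lags, coefficients=coeffs, ci_halfwidth=ci,
                         n_effective=T, zero_variance=True)
    coeffs = sm_acf(x, nlags=max_lag, fft=True)
    return AcfResult(lags=lags, coefficients=coeffs, ci_halfwidth=ci, n_effective=T)


def estimate_period(
    acf_result: AcfResult,
    frame_interval: float,
    alpha: float = 0.05,
    correct_multiplicity: bool = True,
) -> PeriodEstimate:
    """Period from the first significant positive-lag ACF peak.

    Scans lags 1..max_lag-1 for the first strict local maximum (ties broken
    toward the smaller lag) whose coefficient is positive and exceeds the
    significance threshold.  With ``correct_multiplicity`` the per-lag level
    is Šidák-adjusted, alpha' = 1 - (1 - alpha)^(1/m) over the m scanned lags,
    keeping the family-wise false-alarm rate on featureless traces at alpha.
    Absence of a significant peak is a valid result (period None).
    """
    if acf_result.zero_variance:
        return PeriodEstimate(None, None, None, False, float("inf"))
    c = acf_result.coefficients
    m = c.size - 1
    if correct_multiplicity and m > 1:
        alpha_eff = 1.0 - (1.0 - alpha) ** (1.0 / m)
    else:
        alpha_eff = alpha
    z = stats.norm.ppf(1.0 - alpha_eff / 2.0)
    threshold = z / np.sqrt(acf_result.n_effective)
    for k in range(1, m):
        if c[k] > c[k - 1] and c[k] >= c[k + 1] and c[k] > 0 and c[k] > threshold:
            return PeriodEstimate(
                period_min=float(k * frame_interval),
                peak_lag=k,
                peak_coefficient=float(c[k]),
                significant=True,
                threshold=float(threshold),
            )
    return PeriodEstimate(None, None, None, False, float(threshold))
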