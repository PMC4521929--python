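"""Estimators and error models for simulation summaries.

Empirical CDFs carry half-widths from the normal approximation to the
binomial distribution at 99% confidence (the factor 2.56 is the 99.5
percentile of a standard normal); MSD curves carry half-widths of 2.56
standard errors of the mean of squared displacements (switchable to plain
SEM); the anomalous-diffusion exponent is the least-squares slope of
log(MSD) against log(t); histograms use Freedman-Diaconis binning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Z99",
    "SummaryCurves",
    "empirical_cdf",
    "msd_curve",
    "anomaly_exponent",
    "fd_histogram",
    "cdf_difference",
    "histogram_modes",
    "is_bimodal",
]

#: 99.5 percentile of the standard normal; gives 99% two-sided confidence.
Z99 = 2.56


@dataclass
class SummaryCurves:
    """A summary curve (CDF or MSD) with symmetric error half-widths."""

    abscissa: np.ndarray
    estimate: np.ndarray
    halfwidth: np.ndarray
    n: int

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.halfwidth = np.asarray(self.halfwidth, dtype=float)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"abscissa": self.abscissa, "estimate": self.estimate,
                             "error_halfwidth": self.halfwidth, "n": self.n})


def empirical_cdf(samples, eval_points, z=Z99) -> SummaryCurves:
    """Empirical CDF with binomial error half-widths z * sqrt(p(1-p)/n)."""
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    n = samples.size
    if n < 1:
        raise ValueError("need at least one sample")
    eval_points = np.asarray(eval_points, dtype=float)
    p = np.searchsorted(samples, eval_points, side="right") / n
    hw = z * np.sqrt(p * (1.0 - p) / n)
    return SummaryCurves(eval_points, p, hw, n)


def msd_curve(sq_displacements, times, convention="ci99") -> SummaryCurves:
    """MSD with error half-widths from per-replicate squared displacements.

    ``sq_displacements`` has shape (n_replicates, n_times): one squared
    Euclidean displacement from the initial position per replicate and
    evaluation time.  ``convention="ci99"`` gives half-widths 2.56 s/sqrt(n)
    (99% confidence, the default); ``"sem"`` gives
    the plain standard error s/sqrt(n).
    """
    sq = np.atleast_2d(np.asarray(sq_displacements, dtype=float))
    n = sq.shape[0]
    if n < 2:
        raise ValueError("error estimation needs at least two replicates")
    z = Z99 if convention == "ci99" else 1.0
    mean = sq.mean(axis=0)
    s = sq.std(axis=0, ddof=1)
    return SummaryCurves(np.asarray(times, dtype=float), mean, z * s / np.sqrt(n), n)


def anomaly_exponent(msd: SummaryCurves, window=None):
    """Exponent alpha of MSD ~ t^alpha by least squares on log-log values.

    ``window = (t_lo, t_hi)`` restricts the fit (inclusive).  Returns
    ``(alpha, intercept)``; requires at least 3 strictly positive MSD points
    at strictly positive times in the window.
    """
    t = msd.abscissa
    y = msd.estimate
    mask = (t > 0) & (y > 0)
    if window is not None:
        mask &= (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise ValueError("need at least 3 positive points in the fit window")
    alpha, logc = np.polyfit(np.log(t[mask]), np.log(y[mask]), 1)
    return float(alpha), float(np.exp(logc))


def fd_histogram(samples, fallback_bins=64):
    """Histogram with the Freedman-Diaconis bin width 2 IQR n^(-1/3).

    Returns ``(edges, counts)``.  If the IQR is zero the rule degenerates; a
    default equal-width binning over the data range is used with a warning.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("Freedman-Diaconis binning needs at least 4 samples")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    lo, hi = x.min(), x.max()
    if iqr <= 0 or hi == lo:
        warnings.warn("zero interquartile range; falling back to equal-width bins")
        edges = np.linspace(lo, hi if hi > lo else lo + 1.0, fallback_bins + 1)
    else:
        width = 2.0 * iqr * x.size ** (-1.0 / 3.0)
        nbins = max(1, int(np.ceil((hi - lo) / width)))
        edges = lo + width * np.arange(nbins + 1)
    counts, edges = np.histogram(x, bins=edges)
    return edges, counts


def cdf_difference(curve_a: SummaryCurves, curve_b: SummaryCurves, at):
    """Percentage difference |a - b| / a * 100 between two CDFs at one abscissa."""
    a = float(np.interp(at, curve_a.abscissa, curve_a.estimate))
    b = float(np.interp(at, curve_b.abscissa, curve_b.estimate))
    if a == 0:
        raise ValueError("reference CDF is zero at the evaluation point")
    return abs(a - b) / a * 100.0


def histogram_modes(counts, smooth=3, trough_frac=0.8, min_frac=0.1):
    """Locations (bin indices) of local maxima of a smoothed histogram.

    The counts are smoothed with a ``smooth``-bin moving average; a local
    maximum qualifies only if its height is at least ``min_frac`` of the
    global maximum (ignores sampling bumps in the tails) and it is separated
    from the previously accepted one by a trough below ``trough_frac`` times
    the smaller of the two peaks.
    """
    c = np.asarray(counts, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        c = np.convolve(c, kernel, mode="same")
    floor = min_frac * c.max()
    # candidate local maxima (plateau-tolerant)
    cand = [i for i in range(len(c))
            if c[i] >= floor and c[i] > 0
            and (i == 0 or c[i] >= c[i - 1])
            and (i == len(c) - 1 or c[i] > c[i + 1])]
    peaks = []
    for i in cand:
        if not peaks:
            peaks.append(i)
            continue
        j = peaks[-1]
        trough = c[j:i + 1].min()
        smaller = min(c[i], c[j])
        if trough < trough_frac * smaller:
            peaks.append(i)
        elif c[i] > c[j]:
            peaks[-1] = i
    return peaks, c


def is_bimodal(counts, smooth=3, trough_frac=0.8, min_frac=0.1):
    """At least two smoothed local maxima separated by a qualifying trough."""
    peaks, _ = histogram_modes(counts, smooth=smooth, trough_frac=trough_frac,
                               min_frac=min_frac)
    return len(peaks) >= 2
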