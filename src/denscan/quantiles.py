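"""Reference-group quantile estimation and the signed phenotypic distance.

A test subject's measurement value ``t`` is located within the distribution of
the same measurement in a reference group (AMH or Neanderthal crania):

1. reference values outside the Tukey fences ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``
   are discarded as outliers;
2. the i-th order statistic of the remaining N values estimates the
   ``(i - 0.5)/N`` quantile, tied values sharing the mean of their quantiles;
3. quantiles between support points are linearly interpolated, giving a
   piecewise-linear empirical CDF;
4. queries outside the support clamp to ``[0.5/N, 1 - 0.5/N]``, keeping every
   estimated quantile strictly inside (0, 1).

The signed phenotypic distance ``D = 2 s (q - 1/2)`` rescales the quantile
``q`` to (-1, 1) and orients it by the predicted direction ``s`` (+1 when the
phenotype is predicted higher in Denisovans than in the reference group), so
positive distances always mean agreement with the Denisovan prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InsufficientReferenceError",
    "EmpiricalCDF",
    "remove_outliers",
    "build_cdf",
    "estimate_quantile",
    "phenotypic_distance",
]


class InsufficientReferenceError(ValueError):
    """Raised when a reference group is too small to estimate quantiles."""


def remove_outliers(values) -> np.ndarray:
    """Drop values outside the Tukey fences of the input.

    Quartiles are computed by linear interpolation of order statistics at
    positions ``1 + (N-1)p`` (the default convention of mainstream statistical
    software). Requires at least 3 finite values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise InsufficientReferenceError(
            f"need at least 3 finite reference values, got {arr.size}"
        )
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return arr[(arr >= lo) & (arr <= hi)]


@dataclass(frozen=True)
class EmpiricalCDF:
    """Piecewise-linear empirical CDF over an outlier-cleaned reference sample.

    ``support`` holds the distinct sorted reference values; ``quantiles`` the
    plotting-position quantile attached to each (ties collapsed to the mean of
    their ``(i - 0.5)/N`` positions). ``n`` is the post-outlier sample size and
    sets the clamp bounds ``[0.5/n, 1 - 0.5/n]`` used outside the support.
    """

    support: np.ndarray
    quantiles: np.ndarray
    n: int
    degenerate: bool = False

    @property
    def q_lo(self) -> float:
        return 0.5 / self.n

    @property
    def q_hi(self) -> float:
        return 1.0 - 0.5 / self.n

    def __call__(self, t):
        return estimate_quantile(self, t)


def build_cdf(reference_values) -> EmpiricalCDF:
    """Build the interpolated empirical CDF of a reference sample.

    The caller composes with :func:`remove_outliers`; this function uses the
    values as given. All-identical input yields a degenerate CDF flagged as
    such: queries at the point give 0.5, elsewhere the clamp bounds.
    """
    arr = np.sort(np.asarray(reference_values, dtype=float))
    if arr.size < 1 or not np.all(np.isfinite(arr)):
        raise InsufficientReferenceError("reference values must be finite and non-empty")
    n = arr.size
    positions = (np.arange(1, n + 1) - 0.5) / n
    support, inverse = np.unique(arr, return_inverse=True)
    quantiles = np.zeros(support.size)
    counts = np.zeros(support.size)
    np.add.at(quantiles, inverse, positions)
    np.add.at(counts, inverse, 1.0)
    quantiles /= counts
    return EmpiricalCDF(
        support=support, quantiles=quantiles, n=n, degenerate=support.size == 1
    )


def estimate_quantile(cdf: EmpiricalCDF, t):
    """Estimated quantile of ``t`` under ``cdf``; clamped to ``[0.5/n, 1-0.5/n]``.

    Accepts scalars or arrays; NaN queries propagate as NaN.
    """
    t_arr = np.asarray(t, dtype=float)
    if cdf.degenerate:
        point = cdf.support[0]
        q = np.where(
            t_arr == point, 0.5, np.where(t_arr < point, cdf.q_lo, cdf.q_hi)
        )
    else:
        q = np.interp(t_arr, cdf.support, cdf.quantiles, left=cdf.q_lo, right=cdf.q_hi)
        q = np.clip(q, cdf.q_lo, cdf.q_hi)
    q = np.where(np.isnan(t_arr), np.nan, q)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(q)
    return q


def phenotypic_distance(q, s: int):
    """Signed phenotypic distance ``D = 2 s (q - 1/2)``.

    ``q`` is the subject's estimated quantile in the reference distribution and
    ``s`` the predicted direction (+1 = higher in Denisovans). D lies in
    (-1, 1); positive D means the subject sits on the Denisovan-predicted side
    of the reference median.
    """
    if s not in (+1, -1):
        raise ValueError(f"direction s must be +1 or -1, got {s!r}")
    q_arr = np.asarray(q, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (q_arr <= 0.0) | (q_arr >= 1.0)
    if np.any(bad & ~np.isnan(q_arr)):
        raise ValueError("quantile q must lie strictly inside (0, 1)")
    d = 2.0 * s * (q_arr - 0.5)
    if np.isscalar(q) or q_arr.ndim == 0:
        return float(d)
    return d
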