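"""Per-specimen scoring against the Denisovan directional profile.

For each specimen the profile yields a vector of signed phenotypic distances
``d1..dk`` (one per testable prediction). Two one-tailed scores summarise how
strongly the vector leans toward the Denisovan predictions:

* **binomial score** — tests whether the number of strictly positive distances
  exceeds the chance expectation under Binomial(k, 1/2). The default variant is
  the mid-p correction (half weight on the observed count); the plain exact
  tail and a continuity-corrected normal approximation are available.
* **Wilcoxon score** — a one-tailed signed-rank test of whether the median
  distance exceeds zero, using the normal approximation with Pratt handling of
  zeros and tie-corrected variance (matching ``scipy.stats.wilcoxon`` with
  ``zero_method="pratt"``). An exact sign-flip enumeration is provided for
  small k as a cross-check.

Scores are ``S = -log10(P)``; the combined statistic is the Euclidean norm
``sqrt(S_binom^2 + S_wilcoxon^2)``. Because profile measurements are
correlated, the p-values are treated as resemblance scores, not calibrated
significance — calibration is the job of the permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import DenisovanProfile, Group, MeasurementMatrix, ReferenceGroup
from .quantiles import build_cdf, estimate_quantile, phenotypic_distance, remove_outliers

__all__ = [
    "PhenotypicComparison",
    "SpecimenScore",
    "reference_cdf",
    "evaluate_predictions",
    "binomial_score",
    "wilcoxon_score",
    "wilcoxon_exact_p",
    "combined_score",
    "bh_adjust",
    "score_specimen",
    "score_all",
]

P_FLOOR = 1e-300  # avoid -log10(0)


@dataclass(frozen=True)
class PhenotypicComparison:
    """One prediction evaluated on one specimen: value, quantile, distance."""

    prediction_id: str
    observed_value: float
    quantile: float
    distance: float


@dataclass
class SpecimenScore:
    specimen_id: str
    comparisons: tuple[PhenotypicComparison, ...]
    binomial_p: float
    binomial_score: float
    wilcoxon_p: float
    wilcoxon_score: float

    @property
    def n_tested(self) -> int:
        return len(self.comparisons)

    @property
    def n_positive(self) -> int:
        return sum(1 for c in self.comparisons if c.distance > 0)

    @property
    def distances(self) -> np.ndarray:
        return np.array([c.distance for c in self.comparisons])

    @property
    def combined(self) -> float:
        return combined_score(self.binomial_score, self.wilcoxon_score)


def reference_cdf(
    matrix: MeasurementMatrix,
    measurement_id: str,
    reference_ids: Sequence[str],
    exclude: str | None = None,
):
    """Outlier-cleaned empirical CDF of one measurement over a reference group.

    Returns None when fewer than 3 finite reference values remain (the
    comparison is then skipped upstream). ``exclude`` implements leave-one-out
    scoring of reference specimens against their own group.
    """
    col = matrix.col_index(measurement_id)
    vals = [
        matrix.values[matrix.row_index(s), col]
        for s in reference_ids
        if s != exclude
    ]
    vals = np.asarray(vals, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        return None
    return build_cdf(remove_outliers(vals))


def evaluate_predictions(
    specimen_id: str,
    profile: DenisovanProfile,
    matrix: MeasurementMatrix,
    reference_groups: Mapping[ReferenceGroup, Sequence[str]],
    cdf_cache: dict | None = None,
) -> list[PhenotypicComparison]:
    """Evaluate every testable profile prediction on one specimen.

    A prediction is testable when the specimen's measurement is observed and
    the reference group retains at least 3 finite values. If the specimen
    itself belongs to the reference group it is excluded from that group's
    distribution (leave-one-out control scoring). An empty list signals zero
    testable predictions.
    """
    comparisons: list[PhenotypicComparison] = []
    row = matrix.row(specimen_id)
    for pred in profile:
        if pred.measurement_id not in matrix._col:
            continue
        t = row[matrix.col_index(pred.measurement_id)]
        if math.isnan(t):
            continue
        ref_ids = reference_groups.get(pred.reference_group, ())
        exclude = specimen_id if specimen_id in ref_ids else None
        key = (pred.measurement_id, pred.reference_group, exclude)
        if cdf_cache is not None and key in cdf_cache:
            cdf = cdf_cache[key]
        else:
            cdf = reference_cdf(matrix, pred.measurement_id, ref_ids, exclude=exclude)
            if cdf_cache is not None:
                cdf_cache[key] = cdf
        if cdf is None:
            continue
        q = estimate_quantile(cdf, float(t))
        d = phenotypic_distance(q, pred.direction)
        comparisons.append(
            PhenotypicComparison(pred.prediction_id, float(t), q, d)
        )
    return comparisons


# ---------------------------------------------------------------------------
# Binomial score
# ---------------------------------------------------------------------------


def binomial_score(distances, variant: str = "midp") -> tuple[float, float]:
    """One-tailed binomial test on the count of positive phenotypic distances.

    Success = distance strictly greater than zero (an exact zero sits on the
    reference median and counts against the match). Variants:

    * ``midp`` (default): P = P(X > n_pos) + 0.5 P(X = n_pos) under Bin(k, 1/2)
    * ``exact``: P = P(X >= n_pos)
    * ``normal``: continuity-corrected normal approximation

    Returns ``(p, -log10(p))``.
    """
    d = np.asarray(distances, dtype=float)
    k = d.size
    if k == 0:
        raise ValueError("cannot score an empty distance vector")
    n_pos = int(np.sum(d > 0))
    if variant == "midp":
        p = stats.binom.sf(n_pos, k, 0.5) + 0.5 * stats.binom.pmf(n_pos, k, 0.5)
    elif variant == "exact":
        p = stats.binom.sf(n_pos - 1, k, 0.5)
    elif variant == "normal":
        z = (n_pos - 0.5 * k - 0.5) / math.sqrt(0.25 * k)
        p = stats.norm.sf(z)
    else:
        raise ValueError(f"unknown binomial variant {variant!r}")
    p = float(min(max(p, P_FLOOR), 1.0))
    return p, -math.log10(p)


def binomial_midp_table(k: int) -> np.ndarray:
    """Mid-p for every possible positive count 0..k (permutation fast path)."""
    counts = np.arange(k + 1)
    p = stats.binom.sf(counts, k, 0.5) + 0.5 * stats.binom.pmf(counts, k, 0.5)
    return np.clip(p, P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# Wilcoxon score
# ---------------------------------------------------------------------------


def _wilcoxon_pratt_p_2d(D: np.ndarray) -> np.ndarray:
    """Vectorised one-sided (median > 0) signed-rank p for each row of ``D``.

    Normal approximation, Pratt zero handling, tie-corrected variance, no
    continuity correction. Rows with no nonzero value get p = 0.5.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    m, k = D.shape
    absd = np.abs(D)
    r = stats.rankdata(absd, axis=1, method="average")
    r_plus = np.sum(r * (D > 0), axis=1)
    n0 = np.sum(D == 0.0, axis=1).astype(float)
    n = float(k)
    mn = n * (n + 1.0) * 0.25 - n0 * (n0 + 1.0) * 0.25
    var24 = n * (n + 1.0) * (2.0 * n + 1.0) - n0 * (n0 + 1.0) * (2.0 * n0 + 1.0)

    # tie correction: run lengths of equal |d| per row, zero runs excluded
    order = np.sort(absd, axis=1)
    flat = order.ravel()
    first = np.zeros(flat.size, dtype=bool)
    first[:: k] = True
    first[1:] |= flat[1:] != flat[:-1]
    first[:: k] = True
    run_id = np.cumsum(first) - 1
    run_len = np.bincount(run_id).astype(float)
    run_row = np.nonzero(first)[0] // k
    run_val = flat[first]
    weight = (run_len**3 - run_len) * (run_val != 0.0)
    tie_sum = np.bincount(run_row, weights=weight, minlength=m)

    se = np.sqrt((var24 - tie_sum / 2.0) / 24.0)
    p = np.full(m, 0.5)
    ok = se > 0
    z = np.zeros(m)
    z[ok] = (r_plus[ok] - mn[ok]) / se[ok]
    p[ok] = stats.norm.sf(z[ok])
    return np.clip(p, P_FLOOR, 1.0)


def wilcoxon_score(distances) -> tuple[float, float]:
    """One-tailed Wilcoxon signed-rank score for median distance > 0.

    Uses the tie-corrected normal approximation with Pratt handling of zeros.
    An all-zero vector is degenerate and gets p = 0.5 by convention. Returns
    ``(p, -log10(p))``.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot score an empty distance vector")
    p = float(_wilcoxon_pratt_p_2d(d[None, :])[0])
    return p, -math.log10(p)


def wilcoxon_exact_p(distances) -> float:
    """Exact one-sided signed-rank p by enumerating all sign assignments.

    Ranks of |d| are held fixed (Pratt: zeros ranked, never contributing to
    W+); each of the 2^m sign patterns over the m nonzero entries is equally
    likely under the null. Practical for m <= ~20; intended as an oracle for
    the asymptotic path.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot score an empty distance vector")
    r = stats.rankdata(np.abs(d), method="average")
    nz = d != 0
    ranks = r[nz]
    m = int(nz.sum())
    if m == 0:
        return 0.5
    if m > 22:
        raise ValueError(f"exact enumeration infeasible for {m} nonzero values")
    w_obs = float(np.sum(ranks[d[nz] > 0]))
    # subset-sum distribution of W+ over all 2^m sign patterns
    signs = np.array([0.0])
    for rk in ranks:
        signs = np.concatenate([signs, signs + rk])
    return float(np.mean(signs >= w_obs - 1e-12))


# ---------------------------------------------------------------------------
# Combination and multiplicity
# ---------------------------------------------------------------------------


def combined_score(s_binom: float, s_wilcoxon: float) -> float:
    """Euclidean combination ``sqrt(S_b^2 + S_w^2)`` of the two scores."""
    if s_binom < 0 or s_wilcoxon < 0:
        raise ValueError("scores must be nonnegative")
    return math.hypot(s_binom, s_wilcoxon)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------


def score_specimen(
    specimen_id: str,
    profile: DenisovanProfile,
    matrix: MeasurementMatrix,
    reference_groups: Mapping[ReferenceGroup, Sequence[str]],
    binomial_variant: str = "midp",
    cdf_cache: dict | None = None,
) -> SpecimenScore | None:
    """Full profile score for one specimen; None when nothing is testable."""
    comparisons = evaluate_predictions(
        specimen_id, profile, matrix, reference_groups, cdf_cache=cdf_cache
    )
    if not comparisons:
        return None
    d = np.array([c.distance for c in comparisons])
    bp, bs = binomial_score(d, variant=binomial_variant)
    wp, ws = wilcoxon_score(d)
    return SpecimenScore(
        specimen_id=specimen_id,
        comparisons=tuple(comparisons),
        binomial_p=bp,
        binomial_score=bs,
        wilcoxon_p=wp,
        wilcoxon_score=ws,
    )


def score_all(
    profile: DenisovanProfile,
    matrix: MeasurementMatrix,
    records: Sequence,
    binomial_variant: str = "midp",
) -> dict[str, SpecimenScore]:
    """Score every specimen (test subjects and leave-one-out references)."""
    reference_groups = {
        ReferenceGroup.AMH: [r.specimen_id for r in records if r.group is Group.AMH],
        ReferenceGroup.NEANDERTHAL: [
            r.specimen_id for r in records if r.group is Group.NEANDERTHAL
        ],
    }
    cache: dict = {}
    out: dict[str, SpecimenScore] = {}
    for r in records:
        if r.specimen_id not in matrix._row:
            continue
        sc = score_specimen(
            r.specimen_id,
            profile,
            matrix,
            reference_groups,
            binomial_variant=binomial_variant,
            cdf_cache=cache,
        )
        if sc is not None:
            out[r.specimen_id] = sc
    return out
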