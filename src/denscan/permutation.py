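"""Constraint-preserving permutation null for profile-match scores.

The binomial and Wilcoxon scores assume independent comparisons, which cranial
measurements violate (they share overall size and regional anatomy). The
permutation test sidesteps this by asking whether the *actual* profile
measurements are more informative than random draws from the full pool of
available continuous measurements, while conserving the structure of the
observed analysis for each test subject:

* the number of testable predictions ``k_total``;
* the split of predictions across reference groups (AMH vs Neanderthal);
* the split across measurement classes (linear vs nonlinear, i.e. angles and
  ratios);
* the directional structure: every measurement in the pool is sign-aligned to
  the biorbital-breadth anchor (EKB) through the sign of its correlation with
  it, and each permuted slot inherits the original slot's predicted direction
  applied on that aligned scale.

The permutation p-value is the fraction of permuted combined scores greater
than or equal to the observed one (ties counted, conservative); BH adjustment
runs across the family of test subjects with at least five testable
predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import (
    DenisovanProfile,
    Group,
    MeasurementClass,
    MeasurementMatrix,
    ReferenceGroup,
)
from .scoring import (
    _wilcoxon_pratt_p_2d,
    bh_adjust,
    binomial_midp_table,
    reference_cdf,
    score_specimen,
)
from .quantiles import estimate_quantile

__all__ = [
    "PermutationSlotSpec",
    "PermutationResult",
    "orient_measurements",
    "build_slot_spec",
    "sample_permuted_profile",
    "permutation_test",
    "run_permutation_batch",
]

DEFAULT_ANCHOR = "EKB"
NEAR_ZERO_R = 0.05


@dataclass(frozen=True)
class SlotUnit:
    """Prediction slots carried by one original profile measurement.

    A phenotype predicted to differ from both references contributes two
    slots on the same measurement; a permutation replaces the measurement as
    a whole, so the sampled substitute inherits every slot (preserving the
    correlation structure between paired comparisons).
    """

    measurement_class: MeasurementClass
    slots: tuple[tuple[ReferenceGroup, int], ...]  # (reference_group, direction)


@dataclass(frozen=True)
class PermutationSlotSpec:
    """The conserved structure of one subject's observed analysis.

    ``units`` lists the testable original measurements with their prediction
    slots. Every permutation fills exactly these units with distinct sampled
    measurements of matching class, conserving the total prediction count,
    the per-reference-group counts and the linear/nonlinear ratio.
    """

    specimen_id: str
    units: tuple[SlotUnit, ...]

    @property
    def k_total(self) -> int:
        return sum(len(u.slots) for u in self.units)

    @property
    def k_by_reference(self) -> dict[ReferenceGroup, int]:
        out = {g: 0 for g in ReferenceGroup}
        for u in self.units:
            for g, _ in u.slots:
                out[g] += 1
        return out

    @property
    def k_by_class(self) -> dict[MeasurementClass, int]:
        out = {c: 0 for c in MeasurementClass}
        for u in self.units:
            out[u.measurement_class] += len(u.slots)
        return out


@dataclass
class PermutationResult:
    specimen_id: str
    observed_combined: float
    permuted_combined: np.ndarray
    p_raw: float
    n_perm: int
    seed: int | None
    p_adjusted: float | None = None


def orient_measurements(
    matrix: MeasurementMatrix,
    anchor_measurement: str = DEFAULT_ANCHOR,
    method: str = "pearson",
    min_overlap: int = 3,
) -> dict[str, int]:
    """Sign-align every measurement to the anchor via pairwise correlation.

    Returns measurement -> {+1, -1}: the sign of the (Pearson by default)
    correlation with the anchor over pairwise-complete specimens. The anchor
    maps to +1. Near-zero correlations (|r| < 0.05) keep sign +1 and trigger a
    warning; so do measurements sharing fewer than ``min_overlap`` specimens
    with the anchor.
    """
    if anchor_measurement not in matrix._col:
        raise ValueError(f"anchor measurement {anchor_measurement!r} not in matrix")
    anchor = matrix.column(anchor_measurement)
    orientation: dict[str, int] = {}
    for m in matrix.measurement_ids:
        if m == anchor_measurement:
            orientation[m] = +1
            continue
        col = matrix.column(m)
        ok = np.isfinite(anchor) & np.isfinite(col)
        if ok.sum() < min_overlap:
            warnings.warn(
                f"measurement {m!r}: only {int(ok.sum())} specimens shared with "
                f"anchor; orientation defaults to +1",
                stacklevel=2,
            )
            orientation[m] = +1
            continue
        a, b = anchor[ok], col[ok]
        if np.std(a) == 0 or np.std(b) == 0:
            r = 0.0
        elif method == "pearson":
            r = float(np.corrcoef(a, b)[0, 1])
        elif method == "spearman":
            r = float(stats.spearmanr(a, b).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if not np.isfinite(r) or abs(r) < NEAR_ZERO_R:
            if abs(r) < NEAR_ZERO_R:
                warnings.warn(
                    f"measurement {m!r}: near-zero correlation with anchor "
                    f"(r={r:.3f}); orientation defaults to +1",
                    stacklevel=2,
                )
            orientation[m] = +1
        else:
            orientation[m] = +1 if r > 0 else -1
    return orientation


def build_slot_spec(
    specimen_id: str,
    profile: DenisovanProfile,
    matrix: MeasurementMatrix,
    reference_groups: Mapping[ReferenceGroup, Sequence[str]],
) -> PermutationSlotSpec:
    """Slot structure of the subject's observed analysis (testable predictions),
    grouped by source measurement."""
    by_meas: dict[str, list] = {}
    classes: dict[str, MeasurementClass] = {}
    row = matrix.row(specimen_id)
    for pred in profile:
        if pred.measurement_id not in matrix._col:
            continue
        if math.isnan(row[matrix.col_index(pred.measurement_id)]):
            continue
        cdf = reference_cdf(
            matrix,
            pred.measurement_id,
            reference_groups.get(pred.reference_group, ()),
            exclude=specimen_id
            if specimen_id in reference_groups.get(pred.reference_group, ())
            else None,
        )
        if cdf is None:
            continue
        by_meas.setdefault(pred.measurement_id, []).append(
            (pred.reference_group, pred.direction)
        )
        classes[pred.measurement_id] = pred.measurement_class
    units = tuple(
        SlotUnit(measurement_class=classes[m], slots=tuple(slots))
        for m, slots in by_meas.items()
    )
    return PermutationSlotSpec(specimen_id=specimen_id, units=units)


def _subject_pools(
    specimen_id: str,
    matrix: MeasurementMatrix,
    reference_groups: Mapping[ReferenceGroup, Sequence[str]],
    needed_groups: set[ReferenceGroup],
    cdf_cache: dict,
) -> dict[MeasurementClass, list[str]]:
    """Measurements usable in permutations of one subject, keyed by class.

    A measurement qualifies when the subject's value is observed and every
    reference group appearing in the subject's slots retains a valid CDF for
    it, so any sampled measurement can fill any same-class slot.
    """
    row = matrix.row(specimen_id)
    pools: dict[MeasurementClass, list[str]] = {c: [] for c in MeasurementClass}
    for m in matrix.measurement_ids:
        if math.isnan(row[matrix.col_index(m)]):
            continue
        usable = True
        for g in needed_groups:
            ref_ids = reference_groups.get(g, ())
            exclude = specimen_id if specimen_id in ref_ids else None
            key = (m, g, exclude)
            if key not in cdf_cache:
                cdf_cache[key] = reference_cdf(matrix, m, ref_ids, exclude=exclude)
            if cdf_cache[key] is None:
                usable = False
                break
        if usable:
            pools[matrix.measurement_class(m)].append(m)
    return pools


def sample_permuted_profile(
    slot_spec: PermutationSlotSpec,
    measurement_pool: Mapping[MeasurementClass, Sequence[str]],
    orientation: Mapping[str, int],
    rng: np.random.Generator,
) -> list[tuple[str, ReferenceGroup, int]]:
    """Draw one permuted prediction set honouring the slot constraints.

    Each slot unit (one original measurement with its one or two prediction
    slots) receives a random pool measurement of the same class, distinct
    within the permutation; the sampled measurement inherits every slot of
    the unit with effective direction = slot sign × anchor orientation.
    Returns one ``(measurement_id, reference_group, effective_direction)``
    triple per slot.
    """
    by_class: dict[MeasurementClass, list[int]] = {c: [] for c in MeasurementClass}
    for i, u in enumerate(slot_spec.units):
        by_class[u.measurement_class].append(i)
    permuted: list[tuple[str, ReferenceGroup, int]] = []
    assignment: dict[int, str] = {}
    for cls, unit_idx in by_class.items():
        if not unit_idx:
            continue
        pool = list(measurement_pool.get(cls, ()))
        if len(pool) < len(unit_idx):
            raise ValueError(
                f"measurement pool exhausted for class {cls.value}: "
                f"{len(pool)} available, {len(unit_idx)} needed"
            )
        chosen = rng.choice(len(pool), size=len(unit_idx), replace=False)
        for unit_i, pool_i in zip(unit_idx, chosen):
            assignment[unit_i] = pool[int(pool_i)]
    for i, u in enumerate(slot_spec.units):
        m = assignment[i]
        for g, s in u.slots:
            permuted.append((m, g, s * orientation.get(m, +1)))
    return permuted


def permutation_test(
    specimen_id: str,
    profile: DenisovanProfile,
    matrix: MeasurementMatrix,
    reference_groups: Mapping[ReferenceGroup, Sequence[str]],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    anchor_measurement: str = DEFAULT_ANCHOR,
    orientation: Mapping[str, int] | None = None,
    cdf_cache: dict | None = None,
    add_one_smoothing: bool = False,
) -> PermutationResult:
    """Permutation p-value for one subject's combined profile-match score.

    ``p_raw`` is the fraction of the ``n_perm`` permuted combined scores that
    are greater than or equal to the observed one. With
    ``add_one_smoothing`` the estimate becomes ``(count + 1) / (n_perm + 1)``
    (off by default).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else None
        rng = np.random.default_rng(rng)
    cache = cdf_cache if cdf_cache is not None else {}

    observed = score_specimen(
        specimen_id, profile, matrix, reference_groups, cdf_cache=cache
    )
    if observed is None:
        raise ValueError(f"{specimen_id!r} has no testable predictions")
    s_obs = observed.combined

    slot_spec = build_slot_spec(specimen_id, profile, matrix, reference_groups)
    needed = {g for u in slot_spec.units for g, _ in u.slots}
    pools = _subject_pools(specimen_id, matrix, reference_groups, needed, cache)
    if orientation is None:
        orientation = orient_measurements(matrix, anchor_measurement)

    permuted = _permuted_combined_scores(
        specimen_id, slot_spec, pools, orientation, matrix, reference_groups,
        cache, n_perm, rng,
    )
    count = int(np.sum(permuted >= s_obs))
    if add_one_smoothing:
        p_raw = (count + 1) / (n_perm + 1)
    else:
        p_raw = count / n_perm
    return PermutationResult(
        specimen_id=specimen_id,
        observed_combined=s_obs,
        permuted_combined=permuted,
        p_raw=float(p_raw),
        n_perm=n_perm,
        seed=seed,
    )


def _permuted_combined_scores(
    specimen_id: str,
    slot_spec: PermutationSlotSpec,
    pools: Mapping[MeasurementClass, Sequence[str]],
    orientation: Mapping[str, int],
    matrix: MeasurementMatrix,
    reference_groups: Mapping[ReferenceGroup, Sequence[str]],
    cdf_cache: dict,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised permutation engine: returns ``n_perm`` combined scores.

    Precomputes the subject's quantile against every (pool measurement,
    reference group) CDF once; each permutation is then pure index arithmetic
    plus the closed-form scores.
    """
    k = slot_spec.k_total
    row = matrix.row(specimen_id)

    needed_groups = {g for u in slot_spec.units for g, _ in u.slots}

    # quantile lookup tables per class pool and reference group
    q_tab: dict[MeasurementClass, dict[ReferenceGroup, np.ndarray]] = {}
    orient_tab: dict[MeasurementClass, np.ndarray] = {}
    for cls, pool in pools.items():
        q_tab[cls] = {}
        orient_tab[cls] = np.array([orientation.get(m, +1) for m in pool], dtype=float)
        for g in needed_groups:
            exclude = (
                specimen_id
                if specimen_id in reference_groups.get(g, ())
                else None
            )
            qs = np.empty(len(pool))
            for j, m in enumerate(pool):
                cdf = cdf_cache[(m, g, exclude)]
                qs[j] = estimate_quantile(cdf, float(row[matrix.col_index(m)]))
            q_tab[cls][g] = qs

    # flatten units into distance columns
    slot_cols: list[tuple[int, ReferenceGroup, int]] = []  # (unit index, group, s)
    for i, u in enumerate(slot_spec.units):
        for g, s in u.slots:
            slot_cols.append((i, g, s))

    D = np.empty((n_perm, k))
    by_class: dict[MeasurementClass, list[int]] = {c: [] for c in MeasurementClass}
    for i, u in enumerate(slot_spec.units):
        by_class[u.measurement_class].append(i)
    unit_draw: dict[int, np.ndarray] = {}
    for cls, unit_idx in by_class.items():
        if not unit_idx:
            continue
        pool = pools.get(cls, ())
        nc = len(unit_idx)
        if len(pool) < nc:
            raise ValueError(
                f"measurement pool exhausted for class {cls.value}: "
                f"{len(pool)} available, {nc} needed"
            )
        # without-replacement draw per permutation: first nc of a random order
        u_rand = rng.random((n_perm, len(pool)))
        idx = np.argsort(u_rand, axis=1)[:, :nc]
        for j, unit_i in enumerate(unit_idx):
            unit_draw[unit_i] = idx[:, j]
    for col, (unit_i, g, s) in enumerate(slot_cols):
        cls = slot_spec.units[unit_i].measurement_class
        draw = unit_draw[unit_i]
        q = q_tab[cls][g][draw]
        orient = orient_tab[cls][draw]
        D[:, col] = 2.0 * s * orient * (q - 0.5)

    n_pos = np.sum(D > 0, axis=1)
    p_binom = binomial_midp_table(k)[n_pos]
    p_wilcox = _wilcoxon_pratt_p_2d(D)
    return np.hypot(-np.log10(p_binom), -np.log10(p_wilcox))


def run_permutation_batch(
    profile: DenisovanProfile,
    matrix: MeasurementMatrix,
    records: Sequence,
    n_perm: int = 10_000,
    seed: int | None = None,
    min_testable: int = 5,
    anchor_measurement: str = DEFAULT_ANCHOR,
    subjects: Sequence[str] | None = None,
) -> dict[str, PermutationResult]:
    """Permutation tests for all test subjects, with BH across the family.

    The BH family is the set of test subjects carrying at least
    ``min_testable`` testable predictions. Reproducible: each subject draws
    from a child stream of ``seed`` in a fixed order.
    """
    reference_groups = {
        ReferenceGroup.AMH: [r.specimen_id for r in records if r.group is Group.AMH],
        ReferenceGroup.NEANDERTHAL: [
            r.specimen_id for r in records if r.group is Group.NEANDERTHAL
        ],
    }
    if subjects is None:
        subjects = [r.specimen_id for r in records if r.group is Group.TEST]
    cache: dict = {}
    orientation = orient_measurements(matrix, anchor_measurement)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects))
    results: dict[str, PermutationResult] = {}
    for sid, child in zip(subjects, children):
        res = permutation_test(
            sid,
            profile,
            matrix,
            reference_groups,
            n_perm=n_perm,
            rng=np.random.default_rng(child),
            orientation=orientation,
            cdf_cache=cache,
        )
        res.seed = seed
        results[sid] = res

    family = [
        sid
        for sid in results
        if build_slot_spec(sid, profile, matrix, reference_groups).k_total
        >= min_testable
    ]
    if family:
        # p_raw can be exactly 0 under the plain count estimator; floor it so
        # the BH (0, 1] domain guard accepts the family
        raw = np.array([max(results[sid].p_raw, 1e-300) for sid in family])
        adjusted = bh_adjust(raw)
        for sid, a in zip(family, adjusted):
            results[sid].p_adjusted = float(a)
    return results
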