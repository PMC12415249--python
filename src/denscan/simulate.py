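"""Synthetic craniometric studies with the statistical structure the scan assumes.

The generator emulates the features of real comparative craniometric data
that the pipeline's statistics must cope with:

* three reference groups (20 H. erectus, 18 H. sapiens, 15 Neanderthal
  crania) plus a configurable set of test subjects;
* measurements correlated through a latent overall-size factor, with a clean
  biorbital-breadth anchor (``EKB``) loading strongly and positively on it;
  most linear measurements correlate positively with the anchor, a minority
  negatively, and nonlinear measurements (angles/ratios) are size-free;
* additional low-rank "anatomical region" factors plus diagonal noise, so
  measurements are mutually correlated and the independence assumptions of
  the binomial/Wilcoxon scores are genuinely violated;
* random per-group mean shifts that separate the groups in morphospace;
* optional planted Denisovan-like specimens whose profile measurements sit on
  the predicted side of every reference median with a margin expressed in
  within-group standard deviations;
* missing-at-random cells or contiguous preservation-block missingness.

Group means are exchangeable between profile and non-profile measurements, so
a subject drawn from a reference distribution carries no systematic signal on
the profile — the regime in which permutation p-values should be uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    DenisovanProfile,
    Group,
    MeasurementClass,
    MeasurementMatrix,
    ReferenceGroup,
    SpecimenRecord,
    count_testable,
    load_default_profile,
)

__all__ = [
    "SyntheticConfig",
    "generate_study",
    "plant_denisovan_like",
    "inject_missingness",
]

ANCHOR_ID = "EKB"
MOLAR_ID = "M2A"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    The measurement pool defaults to 142 continuous measurements: 118 linear
    with positive anchor correlation, 12 linear with negative anchor
    correlation, and 12 nonlinear (angles/ratios) with no size loading. Group
    sizes follow the three-reference-group design (20/18/15). Effects are in
    within-group SD units.
    """

    n_erectus: int = 20
    n_amh: int = 18
    n_neanderthal: int = 15
    n_test: int = 10
    n_measurements: int = 142
    n_negative_anchor: int = 12
    n_nonlinear: int = 12
    n_residual_factors: int = 3
    residual_loading_sd: float = 0.3
    noise_sd: float = 0.5
    size_loading_lo: float = 0.4
    size_loading_hi: float = 0.9
    anchor_loading: float = 0.9
    group_shift_sd: float = 1.0
    erectus_shift_scale: float = 1.5
    missingness_rate: float = 0.1
    planted_effect_sd: float = 1.5
    test_base_group: Group = Group.AMH
    capacity_mean: float = 1300.0
    capacity_sd: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_erectus", "n_amh", "n_neanderthal", "n_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.missingness_rate < 1.0):
            raise ValueError("missingness_rate must lie in [0, 1)")
        if not np.isfinite(self.planted_effect_sd):
            raise ValueError("planted_effect_sd must be finite")


def _measurement_layout(config: SyntheticConfig, profile: DenisovanProfile):
    """Measurement IDs, classes and size loadings for the study."""
    profile_meas = list(profile.measurement_ids)
    profile_classes = {}
    for p in profile:
        profile_classes[p.measurement_id] = p.measurement_class
    nonlinear_profile = [
        m for m in profile_meas if profile_classes[m] is MeasurementClass.NONLINEAR
    ]
    linear_profile = [
        m for m in profile_meas if profile_classes[m] is MeasurementClass.LINEAR
    ]

    ids: list[str] = []
    classes: dict[str, MeasurementClass] = {}
    ids.append(ANCHOR_ID)
    classes[ANCHOR_ID] = MeasurementClass.LINEAR
    ids.append(MOLAR_ID)
    classes[MOLAR_ID] = MeasurementClass.LINEAR
    for m in linear_profile:
        ids.append(m)
        classes[m] = MeasurementClass.LINEAR
    for m in nonlinear_profile:
        ids.append(m)
        classes[m] = MeasurementClass.NONLINEAR

    n_nonlin_fill = max(config.n_nonlinear - len(nonlinear_profile), 0)
    for i in range(n_nonlin_fill):
        mid = f"A{i + 1:03d}"
        ids.append(mid)
        classes[mid] = MeasurementClass.NONLINEAR
    for i in range(config.n_negative_anchor):
        mid = f"N{i + 1:03d}"
        ids.append(mid)
        classes[mid] = MeasurementClass.LINEAR
    n_fill = config.n_measurements - len(ids)
    if n_fill < 0:
        raise ValueError(
            f"n_measurements={config.n_measurements} too small for the profile "
            f"plus structural measurements ({len(ids)} needed)"
        )
    for i in range(n_fill):
        mid = f"L{i + 1:03d}"
        ids.append(mid)
        classes[mid] = MeasurementClass.LINEAR
    return ids, classes


def generate_study(
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[MeasurementMatrix, list[SpecimenRecord], DenisovanProfile]:
    """Generate a full synthetic study: matrix, specimen records and profile.

    Test subjects are drawn from the ``test_base_group`` distribution with no
    planted profile signal; use :func:`plant_denisovan_like` to add a
    Denisovan-like specimen. Reproducible given ``rng`` (or ``config.seed``).
    """
    config = config or SyntheticConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    profile = load_default_profile()
    ids, classes = _measurement_layout(config, profile)
    for m in profile.measurement_ids:
        if m not in classes:
            raise ValueError(f"profile references absent measurement {m!r}")
    p = len(ids)

    # size loadings: anchor clean and strong; linear fillers positive, the
    # N-block negative, nonlinear size-free
    lam = np.empty(p)
    is_nonlinear = np.array([classes[m] is MeasurementClass.NONLINEAR for m in ids])
    for j, m in enumerate(ids):
        if m == ANCHOR_ID:
            lam[j] = config.anchor_loading
        elif is_nonlinear[j]:
            lam[j] = 0.0
        elif m.startswith("N"):
            lam[j] = -rng.uniform(config.size_loading_lo, config.size_loading_hi)
        else:
            lam[j] = rng.uniform(config.size_loading_lo, config.size_loading_hi)

    B = rng.normal(0.0, config.residual_loading_sd, size=(p, config.n_residual_factors))
    B[ids.index(ANCHOR_ID)] = 0.0  # keep the anchor a clean size proxy

    baseline = np.where(
        is_nonlinear, rng.uniform(80.0, 140.0, p), rng.uniform(40.0, 150.0, p)
    )

    groups = (
        [(Group.H_ERECTUS, config.n_erectus)]
        + [(Group.AMH, config.n_amh)]
        + [(Group.NEANDERTHAL, config.n_neanderthal)]
        + [(Group.TEST, config.n_test)]
    )
    shift = {}
    anchor_j = ids.index(ANCHOR_ID)
    for g, _ in groups:
        if g is Group.AMH:
            shift[g] = np.zeros(p)
        elif g is Group.TEST:
            shift[g] = shift.get(config.test_base_group, np.zeros(p))
        else:
            scale = config.group_shift_sd * (
                config.erectus_shift_scale if g is Group.H_ERECTUS else 1.0
            )
            s = rng.normal(0.0, scale, p)
            s[anchor_j] = 0.0  # anchor carries size only, no group signature
            shift[g] = s
    shift[Group.TEST] = shift[config.test_base_group]

    specimen_ids: list[str] = []
    records: list[SpecimenRecord] = []
    rows: list[np.ndarray] = []
    prefix = {
        Group.H_ERECTUS: "ERE",
        Group.AMH: "AMH",
        Group.NEANDERTHAL: "NEA",
        Group.TEST: "TST",
    }
    for g, n in groups:
        for i in range(n):
            sid = f"{prefix[g]}{i + 1:02d}"
            size = rng.normal()
            w = rng.normal(size=config.n_residual_factors)
            eps = rng.normal(0.0, config.noise_sd, p)
            rows.append(baseline + shift[g] + lam * size + B @ w + eps)
            specimen_ids.append(sid)
            records.append(SpecimenRecord(sid, g, is_adult=True))

    values = np.vstack(rows)
    capacity = {
        sid: float(max(rng.normal(config.capacity_mean, config.capacity_sd), 500.0))
        for sid in specimen_ids
    }
    matrix = MeasurementMatrix(specimen_ids, ids, values, classes, capacity)
    if config.missingness_rate > 0:
        matrix = inject_missingness(matrix, config.missingness_rate, "MCAR", rng)
    for r in records:
        r.n_testable = count_testable(r.specimen_id, profile, matrix)
    return matrix, records, profile


def plant_denisovan_like(
    matrix: MeasurementMatrix,
    profile: DenisovanProfile,
    effect_sd_units: float,
    base_group_ids,
    rng: np.random.Generator | int | None = None,
    specimen_id: str = "PLANTED",
    reference_group_ids=None,
) -> MeasurementMatrix:
    """Append a specimen matching the Denisovan profile with a given margin.

    Non-profile measurements are drawn from the base group's per-measurement
    normal distribution. Each profile measurement is placed on the predicted
    side of every reference median involved, ``effect_sd_units`` within-group
    SDs away (capped at 10 SD, and at the interval midpoint when two
    predictions bound the value from both sides), plus ordinary within-group
    noise. ``reference_group_ids`` maps reference groups to specimen IDs; the
    base group doubles as the AMH reference when omitted.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    effect = min(float(effect_sd_units), 10.0)
    base_rows = np.array([matrix.row(s) for s in base_group_ids], dtype=float)
    base_mean = np.nanmean(base_rows, axis=0)
    base_sd = np.nanstd(base_rows, axis=0, ddof=1)
    base_sd = np.where((base_sd == 0) | ~np.isfinite(base_sd), 1.0, base_sd)

    if reference_group_ids is None:
        reference_group_ids = {ReferenceGroup.AMH: list(base_group_ids)}

    value = base_mean + rng.normal(0.0, base_sd)

    by_meas: dict[str, list] = {}
    for pred in profile:
        by_meas.setdefault(pred.measurement_id, []).append(pred)
    for m, preds in by_meas.items():
        if m not in matrix._col:
            continue
        j = matrix.col_index(m)
        sd = base_sd[j]
        lower, upper = -np.inf, np.inf
        bounds: list[tuple[int, float]] = []
        for pred in preds:
            ref_ids = reference_group_ids.get(
                pred.reference_group, list(base_group_ids)
            )
            ref_vals = np.array(
                [matrix.get(s, m) for s in ref_ids], dtype=float
            )
            ref_vals = ref_vals[np.isfinite(ref_vals)]
            if ref_vals.size == 0:
                continue
            med = float(np.median(ref_vals))
            bounds.append((pred.direction, med))
            if pred.direction == +1:
                lower = max(lower, med)
            else:
                upper = min(upper, med)
        if not bounds:
            continue
        noise = rng.normal(0.0, sd)
        if np.isfinite(lower) and np.isfinite(upper):
            if lower < upper:
                margin = min(effect * sd, (upper - lower) / 2.0)
                value[j] = lower + margin + (noise if effect == 0 else 0.0)
            else:
                # jointly unsatisfiable in this study: honour the first
                # prediction on the measurement, concede the other
                s0, med0 = bounds[0]
                value[j] = med0 + s0 * effect * sd + noise
        elif np.isfinite(lower):
            value[j] = lower + effect * sd + noise
        else:
            value[j] = upper - effect * sd + noise

    out = MeasurementMatrix(
        matrix.specimen_ids + [specimen_id],
        list(matrix.measurement_ids),
        np.vstack([matrix.values, value]),
        dict(matrix.measurement_classes),
        dict(matrix.cranial_capacity),
    )
    return out


def inject_missingness(
    matrix: MeasurementMatrix,
    rate: float,
    pattern: str = "MCAR",
    rng: np.random.Generator | int | None = None,
    n_regions: int = 8,
    max_blocks: int = 3,
) -> MeasurementMatrix:
    """Delete cells missing-at-random or in contiguous preservation blocks.

    ``MCAR`` deletes each cell independently with probability ``rate``.
    ``PRESERVATION_BLOCKS`` splits the measurement list into ``n_regions``
    contiguous anatomical regions and deletes up to ``max_blocks`` whole
    regions per specimen, each region lost with probability ``rate``.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    out = matrix.copy()
    if rate == 0.0:
        return out
    n, p = out.shape
    pattern = pattern.upper()
    if pattern == "MCAR":
        mask = rng.random((n, p)) < rate
        out.values[mask] = np.nan
    elif pattern == "PRESERVATION_BLOCKS":
        bounds = np.linspace(0, p, n_regions + 1).astype(int)
        for i in range(n):
            lost = np.nonzero(rng.random(n_regions) < rate)[0]
            if lost.size > max_blocks:
                lost = rng.choice(lost, size=max_blocks, replace=False)
            for b in lost:
                out.values[i, bounds[b] : bounds[b + 1]] = np.nan
    else:
        raise ValueError(f"unknown missingness pattern {pattern!r}")
    return out
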