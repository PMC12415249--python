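"""Denisovan vs Neanderthal differentiation scoring.

Most profile predictions separate the Neanderthal–Denisovan clade from AMHs
rather than Denisovans from Neanderthals, so a high overall score can reflect
clade membership alone. This module re-scores high-ranking subjects using only
the predictions derived on the Denisovan or Neanderthal lineage (parietal
breadth, maxilloalveolar length and glenoid fossa size greater in Denisovans;
facial breadth, facial protrusion and malar flattening greater in
Neanderthals), optionally augmented by the hallmark larger Denisovan M2 molar
crown area, and places each subject's combined score within the leave-one-out
Neanderthal score distribution as a percentile.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data import (
    DenisovanProfile,
    DirectionalPrediction,
    Lineage,
    MeasurementClass,
    ReferenceGroup,
)
from .quantiles import build_cdf, estimate_quantile, remove_outliers

__all__ = [
    "MOLAR_PREDICTION",
    "differentiation_profile",
    "molar_crown_area",
    "neanderthal_percentile",
]

# M2 crown area, predicted well beyond the Neanderthal range in Denisovans
MOLAR_PREDICTION = DirectionalPrediction(
    prediction_id="PM2",
    phenotype_id="molar_crown_area",
    measurement_id="M2A",
    reference_group=ReferenceGroup.NEANDERTHAL,
    direction=+1,
    lineage_origin=Lineage.DEN_DERIVED,
    measurement_class=MeasurementClass.LINEAR,
)


def differentiation_profile(
    profile: DenisovanProfile, include_molar: bool = False
) -> DenisovanProfile:
    """Restrict a profile to the Den/Nea-derived (clade-distinguishing) predictions.

    With ``include_molar`` the M2 crown-area prediction is appended (seven
    phenotypes in total); subjects lacking M2 data simply skip it through the
    ordinary missing-measurement path.
    """
    derived = tuple(
        p
        for p in profile
        if p.lineage_origin in (Lineage.DEN_DERIVED, Lineage.NEA_DERIVED)
    )
    if not derived:
        raise ValueError(
            "profile carries no Denisovan- or Neanderthal-derived predictions; "
            "lineage annotations missing?"
        )
    if include_molar:
        derived = derived + (MOLAR_PREDICTION,)
    return DenisovanProfile(derived, version=f"{profile.version}-differentiation")


def molar_crown_area(mesiodistal_mm: float, buccolingual_mm: float) -> float:
    """M2 crown area as the mesiodistal × buccolingual product (mm²)."""
    if not (mesiodistal_mm > 0 and buccolingual_mm > 0):
        raise ValueError("molar dimensions must be positive")
    return mesiodistal_mm * buccolingual_mm


def neanderthal_percentile(
    subject_combined_score: float,
    neanderthal_combined_scores: Sequence[float],
) -> float:
    """Percentile of a subject's combined score in the Neanderthal distribution.

    The Neanderthal scores are expected to come from leave-one-out scoring on
    the differentiation profile. The percentile goes through the same
    outlier-cleaned interpolated empirical CDF as the measurement pathway,
    scaled to 0-100.
    """
    scores = np.asarray(neanderthal_combined_scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 3:
        raise ValueError(
            f"need at least 3 Neanderthal scores, got {scores.size}"
        )
    cdf = build_cdf(remove_outliers(scores))
    return 100.0 * estimate_quantile(cdf, float(subject_combined_score))
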