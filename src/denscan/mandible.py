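"""Mandibular validation of the Denisovan profile on Xiahe 1 and Penghu 1.

The two molecularly confirmed Denisovan mandibles let a handful of mandibular
profile predictions be checked directly against published values: each check
compares an observed measurement to a reference comparator (a median or mean
of a named comparison sample) and is CONFIRMED when the observation falls on
the Denisovan-predicted side, CONTRADICTED when it falls on the other side,
and UNTESTABLE when either side is unavailable. The packaged fixture encodes
the printed values and published relations; :func:`validation_summary` turns
check outcomes (optionally pooled with extra confirmed/testable tallies such
as a cranial match count) into confirmation rates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Outcome",
    "MandibularCheck",
    "condylar_area_ellipse",
    "load_mandible_fixture",
    "evaluate_mandibular_checks",
    "validation_summary",
]


class Outcome(str, enum.Enum):
    CONFIRMED = "CONFIRMED"
    CONTRADICTED = "CONTRADICTED"
    UNTESTABLE = "UNTESTABLE"


@dataclass(frozen=True)
class MandibularCheck:
    specimen: str
    prediction_id: str
    measurement: str
    predicted_direction: int
    comparator_group: str
    comparator_kind: str
    outcome: Outcome
    observed_value: float | None = None
    comparator_value: float | None = None
    units: str = ""
    note: str = ""


def condylar_area_ellipse(mediolateral_mm: float, anteroposterior_mm: float) -> float:
    """Condylar head area approximated as an ellipse: π/4 · ML · AP (mm²)."""
    if not (mediolateral_mm > 0 and anteroposterior_mm > 0):
        raise ValueError("condylar dimensions must be positive")
    return math.pi / 4.0 * mediolateral_mm * anteroposterior_mm


def load_mandible_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged (or a user-supplied) mandibular check table."""
    if path is None:
        with resources.as_file(
            resources.files("denscan.resources").joinpath("mandible_checks.tsv")
        ) as p:
            return pd.read_csv(p, sep="\t", comment="#", dtype=str)
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _float_or_none(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    s = str(x).strip()
    if s in ("", "NA", "?", "-"):
        return None
    return float(s)


def evaluate_mandibular_checks(fixture: pd.DataFrame | None = None) -> list[MandibularCheck]:
    """Evaluate each fixture row into a CONFIRMED/CONTRADICTED/UNTESTABLE check.

    Rows with ``evidence_type=numeric`` compare observed vs comparator values
    directly; ``reported_relation`` rows carry the published greater/less
    relation; ``missing`` rows are untestable.
    """
    if fixture is None:
        fixture = load_mandible_fixture()
    required = {
        "specimen",
        "prediction_id",
        "measurement",
        "predicted_direction",
        "comparator_group",
        "comparator_kind",
        "evidence_type",
        "observed_value",
        "comparator_value",
        "relation",
    }
    missing_cols = required - set(fixture.columns)
    if missing_cols:
        raise ValueError(f"mandible fixture lacks columns {sorted(missing_cols)}")
    checks: list[MandibularCheck] = []
    for _, row in fixture.iterrows():
        direction = int(row["predicted_direction"])
        if direction not in (+1, -1):
            raise ValueError(
                f"{row['specimen']}/{row['prediction_id']}: predicted_direction "
                f"must be +1 or -1"
            )
        evidence = str(row["evidence_type"]).strip()
        observed = _float_or_none(row["observed_value"])
        comparator = _float_or_none(row["comparator_value"])
        if evidence == "numeric":
            if observed is None or comparator is None:
                raise ValueError(
                    f"{row['specimen']}/{row['prediction_id']}: numeric check "
                    "needs both observed and comparator values"
                )
            if observed == comparator:
                outcome = Outcome.CONTRADICTED  # on the median is not a match
            else:
                on_predicted_side = (observed > comparator) == (direction == +1)
                outcome = Outcome.CONFIRMED if on_predicted_side else Outcome.CONTRADICTED
        elif evidence == "reported_relation":
            rel = str(row["relation"]).strip().lower()
            if rel not in ("greater", "less"):
                raise ValueError(
                    f"{row['specimen']}/{row['prediction_id']}: relation must be "
                    f"'greater' or 'less', got {rel!r}"
                )
            matches = (rel == "greater") == (direction == +1)
            outcome = Outcome.CONFIRMED if matches else Outcome.CONTRADICTED
        elif evidence == "missing":
            outcome = Outcome.UNTESTABLE
        else:
            raise ValueError(f"unknown evidence_type {evidence!r}")
        checks.append(
            MandibularCheck(
                specimen=str(row["specimen"]),
                prediction_id=str(row["prediction_id"]),
                measurement=str(row["measurement"]),
                predicted_direction=direction,
                comparator_group=str(row["comparator_group"]),
                comparator_kind=str(row["comparator_kind"]),
                outcome=outcome,
                observed_value=observed,
                comparator_value=comparator,
                units=str(row.get("units", "")),
                note=str(row.get("note", "")),
            )
        )
    return checks


def validation_summary(
    checks: list[MandibularCheck],
    extra_tallies: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Confirmation rates per specimen and pooled.

    ``extra_tallies`` maps a label to a (confirmed, testable) pair to pool in
    (e.g. a cranial profile-match count). Percentages are rounded to the
    nearest integer percent. Raises when nothing is testable.
    """
    per_specimen: dict[str, dict] = {}
    confirmed = testable = 0
    for c in checks:
        entry = per_specimen.setdefault(
            c.specimen, {"confirmed": 0, "testable": 0, "untestable": 0}
        )
        if c.outcome is Outcome.UNTESTABLE:
            entry["untestable"] += 1
            continue
        entry["testable"] += 1
        testable += 1
        if c.outcome is Outcome.CONFIRMED:
            entry["confirmed"] += 1
            confirmed += 1
    if testable == 0 and not extra_tallies:
        raise ValueError("no testable checks: confirmation rate undefined")
    for entry in per_specimen.values():
        if entry["testable"]:
            entry["percent_confirmed"] = round(
                100.0 * entry["confirmed"] / entry["testable"]
            )
    summary = {
        "per_specimen": per_specimen,
        "confirmed": confirmed,
        "testable": testable,
        "percent_confirmed": round(100.0 * confirmed / testable) if testable else None,
    }
    if extra_tallies:
        pooled_c, pooled_t = confirmed, testable
        for label, (c_extra, t_extra) in extra_tallies.items():
            if not (0 <= c_extra <= t_extra):
                raise ValueError(f"tally {label!r}: confirmed must be <= testable")
            pooled_c += c_extra
            pooled_t += t_extra
        if pooled_t == 0:
            raise ValueError("no testable checks: confirmation rate undefined")
        summary["pooled_confirmed"] = pooled_c
        summary["pooled_testable"] = pooled_t
        summary["pooled_percent_confirmed"] = round(100.0 * pooled_c / pooled_t)
    return summary
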