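"""Domain model and I/O for directional phenotype profiles and craniometric matrices.

The central objects are:

* :class:`DirectionalPrediction` — a single signed, qualitative prediction that a
  cranial phenotype is higher (``direction=+1``) or lower (``direction=-1``) in
  Denisovans than in a named reference group (anatomically modern humans or
  Neanderthals).
* :class:`DenisovanProfile` — the ordered collection of such predictions.
* :class:`MeasurementMatrix` — a specimens × measurements table of continuous
  craniometric values (mm for linear distances, degrees or dimensionless for
  angles and ratios) with explicit missingness, the unit of all downstream
  computation.
* :class:`SpecimenRecord` — per-specimen metadata: group assignment, adult flag
  and the number of profile predictions testable on that specimen.

Matrices round-trip through CSV, TSV and a minimal NEXUS continuous-characters
dialect (the Morphobank export format family).
"""

from __future__ import annotations

import enum
import io
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceGroup",
    "Lineage",
    "MeasurementClass",
    "Group",
    "DirectionalPrediction",
    "DenisovanProfile",
    "MeasurementMatrix",
    "SpecimenRecord",
    "ProfileError",
    "MatrixFormatError",
    "read_measurement_matrix",
    "write_measurement_matrix",
    "load_profile",
    "load_default_profile",
    "select_test_subjects",
    "normalize_by_cranial_capacity",
    "count_testable",
]

MISSING_MARKERS = {"?", "", "NA", "-", "NaN", "nan"}


class ProfileError(ValueError):
    """Raised when a prediction profile fails validation."""


class MatrixFormatError(ValueError):
    """Raised when a measurement matrix file is malformed."""


class ReferenceGroup(str, enum.Enum):
    AMH = "AMH"
    NEANDERTHAL = "NEANDERTHAL"


class Lineage(str, enum.Enum):
    """Lineage on which the underlying regulatory change is inferred to have arisen."""

    AMH_DERIVED = "AMH_DERIVED"
    NEA_DEN_ANCESTOR = "NEA_DEN_ANCESTOR"
    NEA_DERIVED = "NEA_DERIVED"
    DEN_DERIVED = "DEN_DERIVED"


class MeasurementClass(str, enum.Enum):
    LINEAR = "LINEAR"
    NONLINEAR = "NONLINEAR"


class Group(str, enum.Enum):
    TEST = "TEST"
    AMH = "AMH"
    NEANDERTHAL = "NEANDERTHAL"
    H_ERECTUS = "H_ERECTUS"


@dataclass(frozen=True)
class DirectionalPrediction:
    prediction_id: str
    phenotype_id: str
    measurement_id: str
    reference_group: ReferenceGroup
    direction: int
    lineage_origin: Lineage
    measurement_class: MeasurementClass

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ProfileError(
                f"prediction {self.prediction_id}: direction must be +1 or -1, "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class DenisovanProfile:
    predictions: tuple[DirectionalPrediction, ...]
    version: str = "default"

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    @property
    def phenotype_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.predictions:
            seen.setdefault(p.phenotype_id, None)
        return tuple(seen)

    @property
    def measurement_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.predictions:
            seen.setdefault(p.measurement_id, None)
        return tuple(seen)

    def by_reference(self, group: ReferenceGroup) -> tuple[DirectionalPrediction, ...]:
        return tuple(p for p in self.predictions if p.reference_group is group)


@dataclass
class SpecimenRecord:
    specimen_id: str
    group: Group
    is_adult: bool = True
    n_testable: int = 0

    def __post_init__(self) -> None:
        if self.n_testable < 0:
            raise ValueError(f"{self.specimen_id}: n_testable must be >= 0")


class MeasurementMatrix:
    """Specimens × measurements continuous matrix with explicit missing values.

    Values are stored as a float ndarray with NaN marking missing cells.
    Measurement classes (linear distance vs angle/ratio) travel with the matrix
    so that size normalization and class-stratified permutation both know which
    columns are inherently size-free.
    """

    def __init__(
        self,
        specimen_ids: Sequence[str],
        measurement_ids: Sequence[str],
        values: np.ndarray,
        measurement_classes: dict[str, MeasurementClass] | None = None,
        cranial_capacity: dict[str, float] | None = None,
    ) -> None:
        specimen_ids = list(specimen_ids)
        measurement_ids = list(measurement_ids)
        if len(set(specimen_ids)) != len(specimen_ids):
            dupes = sorted({s for s in specimen_ids if specimen_ids.count(s) > 1})
            raise MatrixFormatError(f"duplicate specimen IDs: {dupes}")
        if len(set(measurement_ids)) != len(measurement_ids):
            dupes = sorted({m for m in measurement_ids if measurement_ids.count(m) > 1})
            raise MatrixFormatError(f"duplicate measurement IDs: {dupes}")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(specimen_ids), len(measurement_ids)):
            raise MatrixFormatError(
                f"value shape {values.shape} does not match "
                f"{len(specimen_ids)} specimens x {len(measurement_ids)} measurements"
            )
        if np.any(np.isinf(values)):
            raise MatrixFormatError("values must be finite or missing (NaN)")
        self.specimen_ids = specimen_ids
        self.measurement_ids = measurement_ids
        self.values = values
        self.measurement_classes = dict(measurement_classes or {})
        for m in self.measurement_classes:
            if m not in set(measurement_ids):
                raise MatrixFormatError(f"class given for unknown measurement {m!r}")
        self.cranial_capacity = dict(cranial_capacity or {})
        for s, c in self.cranial_capacity.items():
            if not (c > 0):
                raise MatrixFormatError(f"cranial capacity for {s!r} must be > 0")
        self._row = {s: i for i, s in enumerate(specimen_ids)}
        self._col = {m: j for j, m in enumerate(measurement_ids)}

    # -- accessors ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, specimen_id: str) -> int:
        try:
            return self._row[specimen_id]
        except KeyError:
            raise KeyError(f"unknown specimen {specimen_id!r}") from None

    def col_index(self, measurement_id: str) -> int:
        try:
            return self._col[measurement_id]
        except KeyError:
            raise KeyError(f"unknown measurement {measurement_id!r}") from None

    def get(self, specimen_id: str, measurement_id: str) -> float:
        return float(self.values[self.row_index(specimen_id), self.col_index(measurement_id)])

    def column(self, measurement_id: str) -> np.ndarray:
        return self.values[:, self.col_index(measurement_id)]

    def row(self, specimen_id: str) -> np.ndarray:
        return self.values[self.row_index(specimen_id), :]

    def measurement_class(self, measurement_id: str) -> MeasurementClass:
        return self.measurement_classes.get(measurement_id, MeasurementClass.LINEAR)

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.specimen_ids, columns=self.measurement_ids)

    def subset(
        self,
        specimen_ids: Sequence[str] | None = None,
        measurement_ids: Sequence[str] | None = None,
    ) -> "MeasurementMatrix":
        specs = list(specimen_ids) if specimen_ids is not None else self.specimen_ids
        meas = list(measurement_ids) if measurement_ids is not None else self.measurement_ids
        ri = [self.row_index(s) for s in specs]
        ci = [self.col_index(m) for m in meas]
        return MeasurementMatrix(
            specs,
            meas,
            self.values[np.ix_(ri, ci)].copy(),
            {m: c for m, c in self.measurement_classes.items() if m in set(meas)},
            {s: c for s, c in self.cranial_capacity.items() if s in set(specs)},
        )

    def copy(self) -> "MeasurementMatrix":
        return MeasurementMatrix(
            list(self.specimen_ids),
            list(self.measurement_ids),
            self.values.copy(),
            dict(self.measurement_classes),
            dict(self.cranial_capacity),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementMatrix):
            return NotImplemented
        return (
            self.specimen_ids == other.specimen_ids
            and self.measurement_ids == other.measurement_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, specimen: str, measurement: str) -> float:
    token = raw.strip()
    if token in MISSING_MARKERS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise MatrixFormatError(
            f"non-numeric cell {raw!r} at specimen {specimen!r}, "
            f"measurement {measurement!r}"
        ) from None


def _read_delimited(text: str, sep: str) -> MeasurementMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError("empty matrix file")
    header = [h.strip() for h in lines[0].split(sep)]
    if len(header) < 2:
        raise MatrixFormatError("expected a specimen_id column plus measurement columns")
    measurement_ids = header[1:]
    specimen_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        cells = ln.split(sep)
        if len(cells) != len(header):
            raise MatrixFormatError(
                f"row {cells[0]!r}: expected {len(header)} cells, got {len(cells)}"
            )
        sid = cells[0].strip()
        specimen_ids.append(sid)
        rows.append(
            [_parse_cell(c, sid, m) for c, m in zip(cells[1:], measurement_ids)]
        )
    return MeasurementMatrix(specimen_ids, measurement_ids, np.array(rows, dtype=float))


_NEXUS_DIM = re.compile(r"DIMENSIONS\s+NTAX\s*=\s*(\d+)\s+NCHAR\s*=\s*(\d+)\s*;", re.I)
_NEXUS_LABELS = re.compile(r"CHARLABELS\s+(.*?);", re.I | re.S)
_NEXUS_MATRIX = re.compile(r"MATRIX\s+(.*?);", re.I | re.S)


def _read_nexus_continuous(text: str) -> MeasurementMatrix:
    """Minimal reader for the DIMENSIONS/FORMAT/CHARLABELS/MATRIX core of a
    CONTINUOUS CHARACTERS block. Anything fancier is rejected."""
    if "DATATYPE" in text.upper() and "CONTINUOUS" not in text.upper():
        raise MatrixFormatError("only DATATYPE=CONTINUOUS NEXUS blocks are supported")
    m_dim = _NEXUS_DIM.search(text)
    if m_dim is None:
        raise MatrixFormatError("NEXUS file lacks a DIMENSIONS statement")
    ntax, nchar = int(m_dim.group(1)), int(m_dim.group(2))
    m_lab = _NEXUS_LABELS.search(text)
    if m_lab is not None:
        measurement_ids = m_lab.group(1).split()
    else:
        measurement_ids = [f"char{j + 1}" for j in range(nchar)]
    if len(measurement_ids) != nchar:
        raise MatrixFormatError(
            f"CHARLABELS lists {len(measurement_ids)} names but NCHAR={nchar}"
        )
    m_mat = _NEXUS_MATRIX.search(text)
    if m_mat is None:
        raise MatrixFormatError("NEXUS file lacks a MATRIX statement")
    specimen_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in m_mat.group(1).splitlines():
        ln = ln.strip()
        if not ln:
            continue
        tokens = ln.replace("'", " ").split()
        sid = tokens[0]
        cells = tokens[1:]
        if len(cells) != nchar:
            raise MatrixFormatError(
                f"NEXUS row {sid!r}: expected {nchar} values, got {len(cells)}"
            )
        specimen_ids.append(sid)
        rows.append([_parse_cell(c, sid, m) for c, m in zip(cells, measurement_ids)])
    if len(specimen_ids) != ntax:
        raise MatrixFormatError(f"NEXUS matrix has {len(specimen_ids)} rows but NTAX={ntax}")
    return MeasurementMatrix(specimen_ids, measurement_ids, np.array(rows, dtype=float))


def read_measurement_matrix(
    path: str | Path,
    dialect: str = "CSV",
    measurement_classes: dict[str, MeasurementClass] | None = None,
) -> MeasurementMatrix:
    """Read a specimens × measurements matrix from CSV, TSV or NEXUS.

    ``measurement_classes`` optionally attaches the linear/nonlinear class of
    each column; unlisted columns default to LINEAR.
    """
    text = Path(path).read_text(encoding="utf-8")
    dialect = dialect.upper()
    if dialect == "CSV":
        matrix = _read_delimited(text, ",")
    elif dialect == "TSV":
        matrix = _read_delimited(text, "\t")
    elif dialect == "NEXUS_CONTINUOUS":
        matrix = _read_nexus_continuous(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if measurement_classes:
        matrix.measurement_classes = dict(measurement_classes)
    return matrix


def write_measurement_matrix(matrix: MeasurementMatrix, path: str | Path, dialect: str = "CSV") -> None:
    """Write a matrix; missing cells become ``NA`` (CSV/TSV) or ``?`` (NEXUS)."""
    dialect = dialect.upper()
    buf = io.StringIO()
    if dialect in ("CSV", "TSV"):
        sep = "," if dialect == "CSV" else "\t"
        buf.write("specimen_id" + sep + sep.join(matrix.measurement_ids) + "\n")
        for i, sid in enumerate(matrix.specimen_ids):
            cells = [
                "NA" if math.isnan(v) else repr(float(v)) for v in matrix.values[i]
            ]
            buf.write(sid + sep + sep.join(cells) + "\n")
    elif dialect == "NEXUS_CONTINUOUS":
        n, k = matrix.shape
        buf.write("#NEXUS\nBEGIN CHARACTERS;\n")
        buf.write(f"DIMENSIONS NTAX={n} NCHAR={k};\n")
        buf.write("FORMAT DATATYPE=CONTINUOUS MISSING=?;\n")
        buf.write("CHARLABELS " + " ".join(matrix.measurement_ids) + ";\n")
        buf.write("MATRIX\n")
        for i, sid in enumerate(matrix.specimen_ids):
            cells = ["?" if math.isnan(v) else repr(float(v)) for v in matrix.values[i]]
            buf.write(sid + " " + " ".join(cells) + "\n")
        buf.write(";\nEND;\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Profile loading
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = [
    "prediction_id",
    "phenotype_id",
    "measurement_id",
    "reference_group",
    "direction",
    "lineage_origin",
    "measurement_class",
]


def load_profile(path: str | Path, version: str | None = None) -> DenisovanProfile:
    """Load a directional prediction profile from a TSV file.

    One prediction per row; the direction column holds +1 / -1 (the sign *s*:
    +1 means the phenotype is predicted to be higher in Denisovans than in the
    row's reference group).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ProfileError(f"profile file {path} is empty") from None
    missing_cols = [c for c in _PROFILE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ProfileError(f"profile file {path} lacks columns {missing_cols}")
    if len(table) == 0:
        raise ProfileError(f"profile file {path} has no predictions")
    predictions = []
    for _, row in table.iterrows():
        try:
            ref = ReferenceGroup(row["reference_group"])
        except ValueError:
            raise ProfileError(
                f"prediction {row['prediction_id']}: unknown reference group "
                f"{row['reference_group']!r}"
            ) from None
        try:
            direction = int(row["direction"])
        except (TypeError, ValueError):
            raise ProfileError(
                f"prediction {row['prediction_id']}: direction {row['direction']!r} "
                "is not an integer"
            ) from None
        predictions.append(
            DirectionalPrediction(
                prediction_id=row["prediction_id"],
                phenotype_id=row["phenotype_id"],
                measurement_id=row["measurement_id"],
                reference_group=ref,
                direction=direction,
                lineage_origin=Lineage(row["lineage_origin"]),
                measurement_class=MeasurementClass(row["measurement_class"]),
            )
        )
    ids = [p.prediction_id for p in predictions]
    if len(set(ids)) != len(ids):
        raise ProfileError("duplicate prediction IDs in profile")
    return DenisovanProfile(tuple(predictions), version=version or path.stem)


def load_default_profile() -> DenisovanProfile:
    """Load the packaged default Denisovan prediction profile.

    The default profile carries 18 directional predictions over 12 cranial
    phenotypes: 12 tested against the AMH reference distribution and 6 against
    the Neanderthal one (the Den/Nea-derived, clade-distinguishing subset).
    """
    with resources.as_file(
        resources.files("denscan.resources").joinpath("profile_default.tsv")
    ) as p:
        return load_profile(p, version="default")


# ---------------------------------------------------------------------------
# Specimen selection and normalization
# ---------------------------------------------------------------------------


def count_testable(
    specimen_id: str, profile: DenisovanProfile, matrix: MeasurementMatrix
) -> int:
    """Number of profile predictions whose measurement is observed for a specimen."""
    row = matrix.row(specimen_id)
    n = 0
    for p in profile:
        if p.measurement_id in matrix._col and not math.isnan(
            row[matrix.col_index(p.measurement_id)]
        ):
            n += 1
    return n


def select_test_subjects(
    records: Iterable[SpecimenRecord], min_testable: int = 5
) -> list[SpecimenRecord]:
    """Apply the specimen-selection criteria to the candidate pool.

    Retains TEST-group records that are adult and carry at least
    ``min_testable`` testable profile predictions; reference-group records are
    not test subjects and are never returned.
    """
    return [
        r
        for r in records
        if r.group is Group.TEST and r.is_adult and r.n_testable >= min_testable
    ]


def normalize_by_cranial_capacity(matrix: MeasurementMatrix) -> MeasurementMatrix:
    """Divide linear measurements by the cube root of cranial capacity.

    Angles and ratios (NONLINEAR class) are inherently size-free and pass
    through unchanged, as does the missingness pattern.
    """
    linear_cols = [
        j
        for j, m in enumerate(matrix.measurement_ids)
        if matrix.measurement_class(m) is MeasurementClass.LINEAR
    ]
    needs_capacity = [
        s
        for i, s in enumerate(matrix.specimen_ids)
        if linear_cols
        and np.any(~np.isnan(matrix.values[i, linear_cols]))
        and s not in matrix.cranial_capacity
    ]
    if needs_capacity:
        raise ValueError(
            "cranial capacity missing for specimens with linear measurements: "
            + ", ".join(needs_capacity)
        )
    out = matrix.copy()
    for i, s in enumerate(out.specimen_ids):
        cap = out.cranial_capacity.get(s)
        if cap is None:
            continue
        out.values[i, linear_cols] = out.values[i, linear_cols] / cap ** (1.0 / 3.0)
    return out
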