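"""Domain types and I/O for paired perimetry (SAP) / OCT test cohorts.

A cohort couples, per subject, one Humphrey 24-2 visual-field test (52
pattern-deviation probability categories, Mean Deviation, Glaucoma Hemifield
Test label) with one circumpapillary OCT scan (256 averaged A-scan RNFL
thickness values in µm, TSNIT order) plus the covariates needed for
normative correction (age, spherical equivalent).

Conventions
-----------
* Right-eye coordinates throughout: ``y_deg`` positive superior. The
  horizontal sign convention is fixed by the blind-spot exclusions at
  ``(15, ±3)``; the extra nasal-step column sits at ``x = -27``.
  Left-eye data must be mirrored by the caller before ingestion; files
  declare ``laterality: RIGHT_CONVENTION`` and the reader enforces it.
* A-scan index ``i`` corresponds to the scan-circle angle ``i * 360/256``
  degrees, index 0 on the temporal horizontal meridian, proceeding
  superiorly (TSNIT order).
* The 52 grid points are kept in a single canonical order (rows superior to
  inferior, ``x`` ascending within a row) so per-point feature vectors are
  comparable across records.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

__all__ = [
    "PDCategory",
    "GHTLabel",
    "Label",
    "Severity",
    "VFPoint",
    "SAPTest",
    "OCTTest",
    "SubjectRecord",
    "Cohort",
    "CohortValidationError",
    "canonical_grid",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

N_ASCANS = 256
N_VF_POINTS = 52
LATERALITY = "RIGHT_CONVENTION"
#: Signal strength must exceed this for an includable OCT test; weaker scans
#: are accepted by the reader but reported in the warning list.
MIN_SIGNAL_STRENGTH = 5


class PDCategory(str, Enum):
    """Pattern-deviation probability-map class of one visual-field point."""

    GE5 = "GE5"    # within normal limits (p >= 5%)
    LT5 = "LT5"    # p < 5%
    LT2 = "LT2"    # p < 2%
    LT1 = "LT1"    # p < 1%
    LT05 = "LT05"  # p < 0.5%


class GHTLabel(str, Enum):
    WNL = "WNL"
    BORDERLINE = "BORDERLINE"
    ONL = "ONL"


class Label(str, Enum):
    HEALTHY = "HEALTHY"
    GLAUCOMA = "GLAUCOMA"


class Severity(str, Enum):
    EARLY = "EARLY"
    MODERATE = "MODERATE"
    ADVANCED = "ADVANCED"


class CohortValidationError(ValueError):
    """A record violated a structural invariant; the message names the field."""


# Row extents of the 24-2 pattern: y -> (x_min, x_max) on the 6-degree
# lattice offset by 3 degrees.  Rows at y=±3 carry the extra nasal-step
# column at x=-27; the blind-spot points (15, ±3) are excluded.
_ROWS: tuple[tuple[int, int, int], ...] = (
    (21, -9, 9),
    (15, -15, 15),
    (9, -21, 21),
    (3, -27, 21),
    (-3, -27, 21),
    (-9, -21, 21),
    (-15, -15, 15),
    (-21, -9, 9),
)
_BLIND_SPOT = {(15, 3), (15, -3)}


def canonical_grid() -> tuple[tuple[int, int], ...]:
    """The 52 right-eye 24-2 locations in canonical order.

    Rows run superior to inferior (y = +21 .. -21); within a row, x
    ascends.  The two blind-spot locations (15, 3) and (15, -3) are
    excluded.
    """
    points = []
    for y, x_min, x_max in _ROWS:
        for x in range(x_min, x_max + 1, 6):
            if (x, y) not in _BLIND_SPOT:
                points.append((x, y))
    return tuple(points)


CANONICAL_GRID = canonical_grid()
_GRID_INDEX = {pt: i for i, pt in enumerate(CANONICAL_GRID)}


def grid_index(x_deg: float, y_deg: float) -> int:
    """Canonical-order index of a grid point; raises on off-grid input."""
    try:
        return _GRID_INDEX[(int(x_deg), int(y_deg))]
    except KeyError:
        raise CohortValidationError(
            f"({x_deg}, {y_deg}) is not one of the 52 canonical 24-2 locations"
        ) from None


@dataclass(frozen=True)
class VFPoint:
    x_deg: int
    y_deg: int
    pd_category: PDCategory

    def __post_init__(self) -> None:
        if (self.x_deg, self.y_deg) not in _GRID_INDEX:
            raise CohortValidationError(
                f"VFPoint ({self.x_deg}, {self.y_deg}) is off the canonical 24-2 grid"
            )
        if not isinstance(self.pd_category, PDCategory):
            object.__setattr__(self, "pd_category", PDCategory(self.pd_category))


@dataclass
class SAPTest:
    """One 24-2 SITA Standard visual-field test."""

    points: tuple[VFPoint, ...]
    md_db: float
    ght_label: GHTLabel

    def __post_init__(self) -> None:
        self.points = tuple(self.points)
        self.ght_label = GHTLabel(self.ght_label)

    def categories_in_canonical_order(self) -> list[PDCategory]:
        by_loc = {(p.x_deg, p.y_deg): p.pd_category for p in self.points}
        return [by_loc[pt] for pt in CANONICAL_GRID]

    @classmethod
    def from_categories(
        cls, categories: Sequence[PDCategory | str], md_db: float, ght_label: GHTLabel | str
    ) -> "SAPTest":
        """Build a test from 52 categories given in canonical grid order."""
        if len(categories) != N_VF_POINTS:
            raise CohortValidationError(
                f"points: expected {N_VF_POINTS}, got {len(categories)}"
            )
        pts = tuple(
            VFPoint(x, y, PDCategory(c)) for (x, y), c in zip(CANONICAL_GRID, categories)
        )
        return cls(points=pts, md_db=float(md_db), ght_label=GHTLabel(ght_label))


@dataclass
class OCTTest:
    """One circumpapillary RNFL scan: 256 averaged A-scan thickness values."""

    ascan_um: tuple[float, ...]
    signal_strength: int
    age_years: float
    se_diopters: float

    def __post_init__(self) -> None:
        self.ascan_um = tuple(float(v) for v in self.ascan_um)


@dataclass
class SubjectRecord:
    subject_id: str
    label: Label
    sap: SAPTest
    oct: OCTTest
    severity: Severity | None = None

    def __post_init__(self) -> None:
        self.label = Label(self.label)
        if self.severity is not None:
            self.severity = Severity(self.severity)


@dataclass
class Cohort:
    records: list[SubjectRecord]
    metadata: dict = field(default_factory=dict)
    #: Non-fatal issues collected at read/validation time (e.g. low signal
    #: strength); never serialized.
    warnings: list[str] = field(default_factory=list, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> list[int]:
        """0/1 class labels (1 = glaucoma) in record order."""
        return [int(r.label is Label.GLAUCOMA) for r in self.records]


# ---------------------------------------------------------------------------
# validation


def _validate_record(rec: SubjectRecord) -> tuple[list[str], list[str]]:
    """Return (errors, warnings) for one record; messages name the field."""
    errors: list[str] = []
    warnings: list[str] = []
    sid = rec.subject_id

    if len(rec.sap.points) != N_VF_POINTS:
        errors.append(f"{sid}: points: expected {N_VF_POINTS}, got {len(rec.sap.points)}")
    else:
        locs = {(p.x_deg, p.y_deg) for p in rec.sap.points}
        if len(locs) != N_VF_POINTS:
            errors.append(f"{sid}: points: duplicate grid locations")
    if not math.isfinite(rec.sap.md_db):
        errors.append(f"{sid}: md_db: not finite")

    n = len(rec.oct.ascan_um)
    if n != N_ASCANS:
        errors.append(f"{sid}: ascan_um: expected {N_ASCANS} values, got {n}")
    else:
        for i, v in enumerate(rec.oct.ascan_um):
            if not (0.0 < v < 400.0):
                errors.append(f"{sid}: ascan_um[{i}]: {v} outside (0, 400) µm")
                break
    if not (0 <= rec.oct.signal_strength <= 10):
        errors.append(f"{sid}: signal_strength: {rec.oct.signal_strength} outside 0..10")
    elif rec.oct.signal_strength <= MIN_SIGNAL_STRENGTH:
        warnings.append(
            f"{sid}: signal_strength: {rec.oct.signal_strength} <= {MIN_SIGNAL_STRENGTH}"
            " (test below inclusion quality)"
        )

    if (rec.label is Label.GLAUCOMA) != (rec.severity is not None):
        errors.append(f"{sid}: severity: must be present iff label is GLAUCOMA")
    return errors, warnings


def validate_cohort(cohort: Cohort) -> list[str]:
    """Validate every record; raises on invariant violations.

    Returns the list of non-fatal warnings (also stored on the cohort).
    """
    errors: list[str] = []
    warnings: list[str] = []
    seen: set[str] = set()
    for rec in cohort.records:
        if rec.subject_id in seen:
            errors.append(f"{rec.subject_id}: subject_id: duplicate")
        seen.add(rec.subject_id)
        e, w = _validate_record(rec)
        errors.extend(e)
        warnings.extend(w)
    if errors:
        raise CohortValidationError("; ".join(errors))
    cohort.warnings = warnings
    return warnings


# ---------------------------------------------------------------------------
# JSON format

_FORMAT_NAME = "glaufuse-cohort"
_FORMAT_VERSION = 1


def _record_to_dict(rec: SubjectRecord) -> dict:
    return {
        "subject_id": rec.subject_id,
        "label": rec.label.value,
        "severity": rec.severity.value if rec.severity else None,
        "sap": {
            "pd_categories": [c.value for c in rec.sap.categories_in_canonical_order()],
            "md_db": rec.sap.md_db,
            "ght_label": rec.sap.ght_label.value,
        },
        "oct": {
            "ascan_um": list(rec.oct.ascan_um),
            "signal_strength": rec.oct.signal_strength,
            "age_years": rec.oct.age_years,
            "se_diopters": rec.oct.se_diopters,
        },
    }


def _record_from_dict(d: dict) -> SubjectRecord:
    sap = SAPTest.from_categories(
        d["sap"]["pd_categories"], d["sap"]["md_db"], d["sap"]["ght_label"]
    )
    oct_ = OCTTest(
        ascan_um=d["oct"]["ascan_um"],
        signal_strength=int(d["oct"]["signal_strength"]),
        age_years=float(d["oct"]["age_years"]),
        se_diopters=float(d["oct"]["se_diopters"]),
    )
    return SubjectRecord(
        subject_id=str(d["subject_id"]),
        label=Label(d["label"]),
        sap=sap,
        oct=oct_,
        severity=Severity(d["severity"]) if d.get("severity") else None,
    )


# ---------------------------------------------------------------------------
# CSV format (flat: one row per subject)

_CSV_META = [
    "subject_id", "label", "severity", "laterality",
    "md_db", "ght_label", "age_years", "se_diopters", "signal_strength",
]
_CSV_PD = [f"pd{i + 1:02d}" for i in range(N_VF_POINTS)]
_CSV_A = [f"a{i + 1:03d}" for i in range(N_ASCANS)]
CSV_HEADER = _CSV_META + _CSV_PD + _CSV_A


def _fmt(value: float, precision: int | None) -> str:
    return repr(float(value)) if precision is None else f"{value:.{precision}f}"


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    format: str = "json",
    um_precision: int | None = None,
) -> None:
    """Write a cohort to ``path`` in the JSON or flat-CSV dialect.

    JSON is lossless (numbers round-trip bit-identically).  CSV writes A-scan
    values at ``um_precision`` decimals when given (full ``repr`` precision
    otherwise).
    """
    path = Path(path)
    if format == "json":
        doc = {
            "format": _FORMAT_NAME,
            "version": _FORMAT_VERSION,
            "laterality": LATERALITY,
            "metadata": cohort.metadata,
            "records": [_record_to_dict(r) for r in cohort.records],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif format == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(CSV_HEADER)
            for rec in cohort.records:
                row = [
                    rec.subject_id,
                    rec.label.value,
                    rec.severity.value if rec.severity else "",
                    LATERALITY,
                    repr(float(rec.sap.md_db)),
                    rec.sap.ght_label.value,
                    repr(float(rec.oct.age_years)),
                    repr(float(rec.oct.se_diopters)),
                    str(rec.oct.signal_strength),
                ]
                row += [c.value for c in rec.sap.categories_in_canonical_order()]
                row += [_fmt(v, um_precision) for v in rec.oct.ascan_um]
                w.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'json' or 'csv')")


def read_cohort(path: str | Path, format: str = "json") -> Cohort:
    """Read and validate a cohort file.

    Malformed files raise a parse error naming the record; invariant
    violations raise :class:`CohortValidationError` naming the subject and
    field.  Non-fatal issues (e.g. signal strength at or below the inclusion
    cut) are collected in ``cohort.warnings``.
    """
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text())
        if doc.get("format") != _FORMAT_NAME:
            raise CohortValidationError(f"{path}: not a {_FORMAT_NAME} file")
        if doc.get("laterality") != LATERALITY:
            raise CohortValidationError(
                f"{path}: laterality must be {LATERALITY}; mirror left-eye data first"
            )
        records = []
        for i, d in enumerate(doc.get("records", [])):
            try:
                records.append(_record_from_dict(d))
            except (KeyError, ValueError) as exc:
                raise CohortValidationError(f"{path}: record {i}: {exc}") from exc
        cohort = Cohort(records=records, metadata=doc.get("metadata", {}))
    elif format == "csv":
        cohort = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'json' or 'csv')")
    validate_cohort(cohort)
    return cohort


def _read_csv(path: Path) -> Cohort:
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortValidationError(f"{path}: empty file, missing header") from None
        if header != CSV_HEADER:
            raise CohortValidationError(f"{path}: unexpected CSV header")
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise CohortValidationError(
                    f"{path}: line {lineno}: expected {len(CSV_HEADER)} fields, got {len(row)}"
                )
            vals = dict(zip(CSV_HEADER, row))
            if vals["laterality"] != LATERALITY:
                raise CohortValidationError(
                    f"{path}: line {lineno}: laterality must be {LATERALITY}"
                )
            try:
                sap = SAPTest.from_categories(
                    [vals[c] for c in _CSV_PD], float(vals["md_db"]), vals["ght_label"]
                )
                oct_ = OCTTest(
                    ascan_um=[float(vals[c]) for c in _CSV_A],
                    signal_strength=int(vals["signal_strength"]),
                    age_years=float(vals["age_years"]),
                    se_diopters=float(vals["se_diopters"]),
                )
                rec = SubjectRecord(
                    subject_id=vals["subject_id"],
                    label=Label(vals["label"]),
                    sap=sap,
                    oct=oct_,
                    severity=Severity(vals["severity"]) if vals["severity"] else None,
                )
            except (ValueError, CohortValidationError) as exc:
                raise CohortValidationError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return Cohort(records=records)
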