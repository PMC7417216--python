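"""Specimen records, CSV I/O and validation for eyespot datasets.

The unit of observation is a single fish specimen: its species, its
standard length (SL, mm) and whether it carries an eyespot.  A subset of
specimens — those photographed with fins exposed and in good enough
condition to digitize — additionally carry eight morphometric
measurements of the eye and the eyespot (maximum diameters in mm, areas
in mm^2, for the eye, the pupil, the eyespot and the eyespot's dark
"pupil").

Validation embodies the operational definition of an eyespot used when
scoring images (an approximately circular dark centre surrounded by a
pale concentric ring over at least 75% of its circumference, at most ten
eyespots per fish) together with elementary measurement geometry: a
pupil sits inside its eye, an eyespot pupil inside its eyespot, and no
digitized area may exceed the circle spanned by the recorded maximum
diameter beyond a small digitization tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

__all__ = [
    "ValidationError",
    "SchemaError",
    "SpecimenRecord",
    "MorphometricRecord",
    "Dataset",
    "RowRejection",
    "read_specimens",
    "write_specimens",
    "partition_by_presence",
    "validate_eyespot_criteria",
    "GEOMETRY_TOL",
    "REQUIRED_COLUMNS",
    "MORPHOMETRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Relative tolerance for the area-versus-diameter consistency check.
#: A digitized ellipse can never exceed the circle of its own maximum
#: diameter; 5% headroom absorbs tracing noise.
GEOMETRY_TOL = 0.05

#: Maximum number of eyespots an individual may carry and still count as
#: eyespot-bearing under the scoring criteria.
MAX_EYESPOTS = 10

#: Minimum fraction of the dark centre's circumference that the pale
#: ring must cover.
MIN_RING_COVERAGE = 0.75

REQUIRED_COLUMNS = (
    "species_id",
    "specimen_id",
    "standard_length_mm",
    "eyespot_present",
)

MORPHOMETRIC_COLUMNS = (
    "eye_diameter_mm",
    "pupil_diameter_mm",
    "eyespot_diameter_mm",
    "eyespot_pupil_diameter_mm",
    "eye_area_mm2",
    "pupil_area_mm2",
    "eyespot_area_mm2",
    "eyespot_pupil_area_mm2",
)

OPTIONAL_COLUMNS = ("n_eyespots", "total_length_mm", "source")


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


class SchemaError(ValidationError):
    """The input file does not have the expected structure."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One fish: identity, body size and eyespot state.

    ``total_length_mm`` is stored when supplied but never used in any
    analysis; standard length is the size variable throughout.
    """

    species_id: str
    specimen_id: str
    standard_length_mm: float
    eyespot_present: bool
    n_eyespots: int | None = None
    total_length_mm: float | None = None
    source: str | None = None

    def validation_errors(self) -> list[str]:
        errors: list[str] = []
        if not self.species_id:
            errors.append("species_id is empty")
        if not self.specimen_id:
            errors.append("specimen_id is empty")
        if not (self.standard_length_mm > 0) or not math.isfinite(
            self.standard_length_mm
        ):
            errors.append(
                f"standard_length_mm must be a positive finite number, "
                f"got {self.standard_length_mm!r}"
            )
        if self.n_eyespots is not None:
            if self.n_eyespots < 0:
                errors.append(f"n_eyespots must be >= 0, got {self.n_eyespots}")
            elif self.n_eyespots > MAX_EYESPOTS:
                errors.append(
                    f"n_eyespots = {self.n_eyespots} exceeds the maximum of "
                    f"{MAX_EYESPOTS} for an eyespot-bearing fish"
                )
            if (self.n_eyespots >= 1) != bool(self.eyespot_present):
                errors.append(
                    f"n_eyespots = {self.n_eyespots} is inconsistent with "
                    f"eyespot_present = {self.eyespot_present}"
                )
        return errors

    def validate(self) -> "SpecimenRecord":
        errors = self.validation_errors()
        if errors:
            raise ValidationError("; ".join(errors))
        return self


# (diameter column, area column) pairs for the circle bound check.
_FEATURE_PAIRS = (
    ("eye_diameter_mm", "eye_area_mm2"),
    ("pupil_diameter_mm", "pupil_area_mm2"),
    ("eyespot_diameter_mm", "eyespot_area_mm2"),
    ("eyespot_pupil_diameter_mm", "eyespot_pupil_area_mm2"),
)


@dataclass(frozen=True)
class MorphometricRecord:
    """The eight eye/eyespot measurements of one well-preserved specimen.

    Diameters are maximum diameters in mm; areas are digitized feature
    areas in mm^2.  For multi-eyespot fish the measurements refer to the
    largest eyespot.
    """

    specimen: SpecimenRecord
    eye_diameter_mm: float
    pupil_diameter_mm: float
    eyespot_diameter_mm: float
    eyespot_pupil_diameter_mm: float
    eye_area_mm2: float
    pupil_area_mm2: float
    eyespot_area_mm2: float
    eyespot_pupil_area_mm2: float

    def validation_errors(self, tol: float = GEOMETRY_TOL) -> list[str]:
        errors: list[str] = []
        for name in MORPHOMETRIC_COLUMNS:
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                errors.append(f"{name} must be positive and finite, got {value!r}")
        if errors:
            return errors
        if not self.pupil_diameter_mm < self.eye_diameter_mm:
            errors.append("pupil diameter must be smaller than eye diameter")
        if not self.pupil_area_mm2 < self.eye_area_mm2:
            errors.append("pupil area must be smaller than eye area")
        if not self.eyespot_pupil_diameter_mm < self.eyespot_diameter_mm:
            errors.append(
                "eyespot pupil diameter must be smaller than eyespot diameter"
            )
        if not self.eyespot_pupil_area_mm2 < self.eyespot_area_mm2:
            errors.append("eyespot pupil area must be smaller than eyespot area")
        for dia_name, area_name in _FEATURE_PAIRS:
            dia = getattr(self, dia_name)
            area = getattr(self, area_name)
            bound = math.pi * (dia / 2.0) ** 2 * (1.0 + tol)
            if area > bound:
                errors.append(
                    f"{area_name} = {area:.6g} exceeds the maximum-diameter "
                    f"circle bound {bound:.6g} implied by {dia_name} = {dia:.6g}"
                )
        sl = self.specimen.standard_length_mm
        for dia_name, _ in _FEATURE_PAIRS:
            if not getattr(self, dia_name) < sl:
                errors.append(f"{dia_name} must be smaller than standard length")
        return errors

    def validate(self, tol: float = GEOMETRY_TOL) -> "MorphometricRecord":
        errors = self.validation_errors(tol=tol)
        if errors:
            raise ValidationError("; ".join(errors))
        return self


@dataclass(frozen=True)
class RowRejection:
    """Diagnostic for one rejected CSV row (0-based data row index)."""

    row: int
    specimen_id: str
    reason: str


@dataclass
class Dataset:
    """A validated specimen table plus its measurable-fin subset."""

    records: list[SpecimenRecord] = field(default_factory=list)
    morphometrics: list[MorphometricRecord] = field(default_factory=list)
    rejections: list[RowRejection] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.records)

    @property
    def n_species(self) -> int:
        return len({r.species_id for r in self.records})

    @property
    def n_morphometric(self) -> int:
        return len(self.morphometrics)

    @property
    def n_morphometric_species(self) -> int:
        return len({m.specimen.species_id for m in self.morphometrics})

    def species(self) -> list[str]:
        return sorted({r.species_id for r in self.records})

    def presence_counts(self) -> dict[str, float]:
        """Counts and percentages of eyespot-bearing vs lacking specimens."""
        n_with = sum(r.eyespot_present for r in self.records)
        n_without = self.n_samples - n_with
        pct_with = 100.0 * n_with / self.n_samples if self.n_samples else float("nan")
        return {
            "n_samples": self.n_samples,
            "n_with": n_with,
            "n_without": n_without,
            "pct_with": pct_with,
            "pct_without": 100.0 - pct_with if self.n_samples else float("nan"),
        }

    def summary(self) -> dict[str, int]:
        return {
            "n_species": self.n_species,
            "n_samples": self.n_samples,
            "n_morphometric_species": self.n_morphometric_species,
            "n_morphometric_samples": self.n_morphometric,
            "n_rejected_rows": len(self.rejections),
        }

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical CSV column layout."""
        morph_by_key = {
            (m.specimen.species_id, m.specimen.specimen_id): m
            for m in self.morphometrics
        }
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "species_id": rec.species_id,
                "specimen_id": rec.specimen_id,
                "standard_length_mm": rec.standard_length_mm,
                "eyespot_present": int(rec.eyespot_present),
            }
            if rec.n_eyespots is not None:
                row["n_eyespots"] = rec.n_eyespots
            if rec.total_length_mm is not None:
                row["total_length_mm"] = rec.total_length_mm
            if rec.source is not None:
                row["source"] = rec.source
            morph = morph_by_key.get((rec.species_id, rec.specimen_id))
            if morph is not None:
                for name in MORPHOMETRIC_COLUMNS:
                    row[name] = getattr(morph, name)
            rows.append(row)
        return pd.DataFrame(rows)


def _coerce_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str) and value.strip() in ("0", "1"):
        return bool(int(value.strip()))
    raise ValidationError(f"eyespot_present must be 0 or 1, got {value!r}")


def read_specimens(
    path: str | Path, *, tol: float = GEOMETRY_TOL, strict: bool = False
) -> Dataset:
    """Read a specimen CSV into a validated :class:`Dataset`.

    Rows violating record invariants are rejected and reported through
    ``Dataset.rejections`` (or raised immediately when ``strict``).
    Lines starting with ``#`` are treated as comments.

    Raises
    ------
    SchemaError
        If the file is empty or a required column is missing.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty or has no header") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    present_morph = [c for c in MORPHOMETRIC_COLUMNS if c in frame.columns]
    if present_morph and len(present_morph) != len(MORPHOMETRIC_COLUMNS):
        absent = sorted(set(MORPHOMETRIC_COLUMNS) - set(present_morph))
        raise SchemaError(
            f"{path}: morphometric columns must be given all together; "
            f"missing {absent}"
        )

    ds = Dataset()
    for i, row in frame.iterrows():
        specimen_id = str(row.get("specimen_id", ""))
        try:
            rec = SpecimenRecord(
                species_id=str(row["species_id"]),
                specimen_id=specimen_id,
                standard_length_mm=float(row["standard_length_mm"]),
                eyespot_present=_coerce_bool(row["eyespot_present"]),
                n_eyespots=(
                    int(row["n_eyespots"])
                    if "n_eyespots" in frame.columns and pd.notna(row["n_eyespots"])
                    else None
                ),
                total_length_mm=(
                    float(row["total_length_mm"])
                    if "total_length_mm" in frame.columns
                    and pd.notna(row["total_length_mm"])
                    else None
                ),
                source=(
                    str(row["source"])
                    if "source" in frame.columns and pd.notna(row["source"])
                    else None
                ),
            ).validate()
            morph = None
            if present_morph and all(pd.notna(row[c]) for c in MORPHOMETRIC_COLUMNS):
                morph = MorphometricRecord(
                    specimen=rec,
                    **{c: float(row[c]) for c in MORPHOMETRIC_COLUMNS},
                ).validate(tol=tol)
        except (ValidationError, ValueError, TypeError) as exc:
            if strict:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
            ds.rejections.append(
                RowRejection(row=int(i), specimen_id=specimen_id, reason=str(exc))
            )
            continue
        ds.records.append(rec)
        if morph is not None:
            ds.morphometrics.append(morph)

    logger.info(
        "read %s: %d species, %d specimens (%d with full morphometrics), "
        "%d rows rejected",
        path,
        ds.n_species,
        ds.n_samples,
        ds.n_morphometric,
        len(ds.rejections),
    )
    return ds


def write_specimens(ds: Dataset, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write a Dataset back to the canonical CSV layout."""
    path = Path(path)
    frame = ds.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def partition_by_presence(ds: Dataset) -> tuple[Dataset, Dataset]:
    """Split into (with-eyespot, without-eyespot) specimen datasets.

    The two partitions are disjoint and jointly exhaust the records; a
    species undergoing an ontogenetic transition appears in both.
    """
    if not ds.records:
        raise ValidationError("cannot partition an empty dataset")
    with_es = Dataset(
        records=[r for r in ds.records if r.eyespot_present],
        morphometrics=[m for m in ds.morphometrics if m.specimen.eyespot_present],
    )
    without_es = Dataset(
        records=[r for r in ds.records if not r.eyespot_present],
        morphometrics=[m for m in ds.morphometrics if not m.specimen.eyespot_present],
    )
    return with_es, without_es


def validate_eyespot_criteria(
    ring_coverage_fraction: float, n_eyespots: int, is_circular: bool
) -> bool:
    """Score operator annotations against the eyespot definition.

    True iff the marking is circular/elliptic, its pale ring covers at
    least 75% of the dark centre's circumference, and the fish carries
    between 1 and 10 eyespots.
    """
    if not 0.0 <= ring_coverage_fraction <= 1.0:
        raise ValidationError(
            f"ring coverage must lie in [0, 1], got {ring_coverage_fraction!r}"
        )
    return (
        bool(is_circular)
        and ring_coverage_fraction >= MIN_RING_COVERAGE
        and 1 <= n_eyespots <= MAX_EYESPOTS
    )
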