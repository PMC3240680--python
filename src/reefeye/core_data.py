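"""Specimen-level data model, CSV I/O, and preprocessing to species tables.

The analysis pipeline starts from a specimen table: one row per fish, with
taxonomic metadata, a diel-activity class (nocturnal or diurnal), body size,
and five eye measurements per eye side (left/right): eyeball diameter (ED),
axial length (AL), horizontal lens diameter (LD), and the largest and
smallest pupil diameters (PDmax, PDmin), all in millimetres.

Preprocessing follows a fixed recipe: per-specimen averages of the two eye
sides, unweighted species means of those specimen averages, then a
log10 transform rounded to four significant figures. Ratio statistics
(see :mod:`reefeye.optics`) are computed from the untransformed species
means instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EYE_TRAITS",
    "LOG_TRAIT_COLUMNS",
    "ANGUILLIFORM_FAMILIES",
    "DIEL_CLASSES",
    "EyeMeasurements",
    "SpecimenRecord",
    "SchemaError",
    "ValidationError",
    "read_specimen_table",
    "write_specimen_table",
    "specimen_eye_average",
    "species_means",
    "log_transform",
    "round_sig",
    "subset",
]

#: canonical eye-trait short names, in measurement order
EYE_TRAITS: tuple[str, ...] = ("ed", "al", "ld", "pdmax", "pdmin")

#: log-table columns produced by :func:`log_transform`
LOG_TRAIT_COLUMNS: tuple[str, ...] = (
    "log_body_mass",
    "log_ed",
    "log_al",
    "log_ld",
    "log_pdmax",
    "log_pdmin",
)

#: eel-like families excluded from the eye-size vs body-mass regression;
#: their elongated bodies make body mass a misleading size proxy
ANGUILLIFORM_FAMILIES: frozenset[str] = frozenset(
    {"Muraenidae", "Congridae", "Ophichthidae"}
)

DIEL_CLASSES: tuple[str, str] = ("nocturnal", "diurnal")


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ValidationError(ValueError):
    """A row violates a data invariant (named in the message)."""


@dataclass
class EyeMeasurements:
    """Measurements of a single eye (mm); any trait may be missing (None)."""

    ed: float | None = None
    al: float | None = None
    ld: float | None = None
    pdmax: float | None = None
    pdmin: float | None = None

    def get(self, trait: str) -> float | None:
        return getattr(self, trait)

    def is_empty(self) -> bool:
        return all(self.get(t) is None for t in EYE_TRAITS)

    def validate(self, context: str = "") -> None:
        for t in EYE_TRAITS:
            v = self.get(t)
            if v is not None and not (v > 0):
                raise ValidationError(f"{context}: non-positive {t} = {v!r}")
        if self.pdmin is not None and self.pdmax is not None:
            if self.pdmin > self.pdmax:
                raise ValidationError(
                    f"{context}: pdmin ({self.pdmin}) > pdmax ({self.pdmax})"
                )


@dataclass
class SpecimenRecord:
    """One individual fish with per-eye raw measurements and metadata."""

    specimen_id: str
    species_id: str
    family: str
    diel_class: str
    standard_length: float  # mm
    body_mass: float  # g
    left: EyeMeasurements = field(default_factory=EyeMeasurements)
    right: EyeMeasurements = field(default_factory=EyeMeasurements)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ctx = f"specimen {self.specimen_id!r}"
        if self.diel_class not in DIEL_CLASSES:
            raise ValidationError(
                f"{ctx}: diel_class must be one of {DIEL_CLASSES}, "
                f"got {self.diel_class!r}"
            )
        for name, v in (("standard_length", self.standard_length),
                        ("body_mass", self.body_mass)):
            if not (v > 0):
                raise ValidationError(f"{ctx}: non-positive {name} = {v!r}")
        self.left.validate(f"{ctx} left eye")
        self.right.validate(f"{ctx} right eye")
        if self.left.is_empty() and self.right.is_empty():
            raise ValidationError(f"{ctx}: both eye sides missing")


# ---------------------------------------------------------------------------
# CSV I/O

#: canonical CSV columns (UTF-8, "." decimal, empty cell = missing)
CANONICAL_COLUMNS: dict[str, str] = {
    "specimen_id": "specimen_id",
    "species_id": "species",
    "family": "family",
    "diel_class": "diel",
    "standard_length": "standard_length_mm",
    "body_mass": "body_mass_g",
    **{
        f"{side}_{t}": f"{side}_{t}_mm"
        for side in ("left", "right")
        for t in EYE_TRAITS
    },
}

_REQUIRED_FIELDS = (
    "specimen_id",
    "species_id",
    "family",
    "diel_class",
    "standard_length",
    "body_mass",
)


def read_specimen_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[SpecimenRecord]:
    """Read a specimen CSV into validated :class:`SpecimenRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row; missing eye-side cells are empty.
    schema
        Optional map from canonical field names (keys of
        ``CANONICAL_COLUMNS``) to the CSV's column names. Defaults to the
        canonical column names. Eye-side columns absent from the schema (or
        from the file) yield absent measurements, never zeros.

    Raises
    ------
    SchemaError
        If a required metadata column is missing.
    ValidationError
        If a row violates an invariant (non-positive value, PDmin > PDmax,
        duplicate specimen_id, no eye side present); the message names the
        offending specimen.
    """
    colmap = dict(CANONICAL_COLUMNS)
    if schema is not None:
        colmap.update(schema)
    df = pd.read_csv(path)
    for f_name in _REQUIRED_FIELDS:
        if colmap[f_name] not in df.columns:
            raise SchemaError(
                f"required column {colmap[f_name]!r} (field {f_name}) missing"
            )

    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row[colmap["specimen_id"]])
        if sid in seen:
            raise ValidationError(f"duplicate specimen_id {sid!r}")
        seen.add(sid)

        def _meas(side: str) -> EyeMeasurements:
            vals = {}
            for t in EYE_TRAITS:
                col = colmap.get(f"{side}_{t}")
                if col is not None and col in df.columns:
                    v = row[col]
                    vals[t] = None if pd.isna(v) else float(v)
                else:
                    vals[t] = None
            return EyeMeasurements(**vals)

        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species_id=str(row[colmap["species_id"]]),
                family=str(row[colmap["family"]]),
                diel_class=str(row[colmap["diel_class"]]),
                standard_length=float(row[colmap["standard_length"]]),
                body_mass=float(row[colmap["body_mass"]]),
                left=_meas("left"),
                right=_meas("right"),
            )
        )
    return records


def specimens_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with the canonical CSV columns."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            CANONICAL_COLUMNS["specimen_id"]: r.specimen_id,
            CANONICAL_COLUMNS["species_id"]: r.species_id,
            CANONICAL_COLUMNS["family"]: r.family,
            CANONICAL_COLUMNS["diel_class"]: r.diel_class,
            CANONICAL_COLUMNS["standard_length"]: r.standard_length,
            CANONICAL_COLUMNS["body_mass"]: r.body_mass,
        }
        for side in ("left", "right"):
            eye: EyeMeasurements = getattr(r, side)
            for t in EYE_TRAITS:
                row[CANONICAL_COLUMNS[f"{side}_{t}"]] = eye.get(t)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS.values()))


def write_specimen_table(records: Iterable[SpecimenRecord],
                         path: str | Path) -> None:
    """Write records to the canonical CSV (empty cell = missing value)."""
    specimens_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def specimen_eye_average(rec: SpecimenRecord) -> dict[str, float]:
    """Average the left and right eye of one specimen, trait by trait.

    A trait present on both sides is the arithmetic mean of the two; a trait
    present on one side passes through. A trait absent on both sides raises
    :class:`ValidationError`.
    """
    out: dict[str, float] = {}
    for t in EYE_TRAITS:
        lv, rv = rec.left.get(t), rec.right.get(t)
        if lv is None and rv is None:
            raise ValidationError(
                f"specimen {rec.specimen_id!r}: trait {t} absent on both sides"
            )
        out[t] = lv if rv is None else rv if lv is None else 0.5 * (lv + rv)
    return out


def species_means(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Unweighted species means of per-specimen eye averages.

    Returns one row per species with columns ``species_id, family,
    diel_class, n_specimens, body_mass, ed, al, ld, pdmax, pdmin`` (mass in
    g, eye traits in mm). The diel class must be consistent within a species.
    """
    by_species: dict[str, list[SpecimenRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.species_id not in by_species:
            by_species[r.species_id] = []
            order.append(r.species_id)
        by_species[r.species_id].append(r)

    rows = []
    for sp in order:
        recs = by_species[sp]
        classes = {r.diel_class for r in recs}
        if len(classes) > 1:
            raise ValidationError(
                f"species {sp!r} has conflicting diel_class values: "
                f"{sorted(classes)}"
            )
        families = {r.family for r in recs}
        if len(families) > 1:
            raise ValidationError(
                f"species {sp!r} has conflicting family values: "
                f"{sorted(families)}"
            )
        avgs = [specimen_eye_average(r) for r in recs]
        row = {
            "species_id": sp,
            "family": recs[0].family,
            "diel_class": recs[0].diel_class,
            "n_specimens": len(recs),
            "body_mass": float(np.mean([r.body_mass for r in recs])),
        }
        for t in EYE_TRAITS:
            row[t] = float(np.mean([a[t] for a in avgs]))
        rows.append(row)
    return pd.DataFrame(rows)


def round_sig(x: float, n: int = 4) -> float:
    """Round ``x`` to ``n`` significant figures of its decimal representation.

    The convention is applied to the signed value, so e.g.
    ``round_sig(-1.154901, 4) == -1.155`` (significant digits 1, 1, 5, 5) —
    the same result as formatting with ``%.4g``. Zero maps to zero.
    """
    if x == 0 or not math.isfinite(x):
        return x
    magnitude = math.ceil(math.log10(abs(x)))
    # values like 1.0 (log10 exactly 0) need the exponent bumped by one
    if abs(x) >= 10.0 ** magnitude:
        magnitude += 1
    return round(x, n - magnitude)


def log_transform(
    species: pd.DataFrame,
    anguilliform_families: Iterable[str] = ANGUILLIFORM_FAMILIES,
) -> pd.DataFrame:
    """log10-transform species trait means, rounded to 4 significant figures.

    Takes the output of :func:`species_means` and returns a table with
    ``species_id, family, diel_class, anguilliform_flag`` plus log10 columns
    for body mass and the five eye traits. Rounding is to significant
    figures of the signed log value, not decimal places (see
    :func:`round_sig`).
    """
    traits = ("body_mass",) + EYE_TRAITS
    for t in traits:
        bad = species[species[t] <= 0]
        if len(bad):
            raise ValidationError(
                f"non-positive {t} for species "
                f"{bad['species_id'].tolist()}: log10 undefined"
            )
    ang = frozenset(anguilliform_families)
    out = species[["species_id", "family", "diel_class"]].copy()
    out["anguilliform_flag"] = species["family"].isin(ang).to_numpy()
    for t in traits:
        out[f"log_{t}"] = [
            round_sig(math.log10(v), 4) for v in species[t].to_numpy()
        ]
    return out


def subset(table: pd.DataFrame,
           predicate: Callable[[pd.Series], bool] | pd.Series | np.ndarray,
           ) -> pd.DataFrame:
    """Rows of ``table`` satisfying ``predicate``, original order preserved.

    ``predicate`` is either a boolean mask aligned with the table or a
    callable applied per row. An empty result is permitted with a warning.
    """
    if callable(predicate):
        mask = table.apply(predicate, axis=1).astype(bool)
    else:
        mask = pd.Series(np.asarray(predicate, dtype=bool), index=table.index)
    out = table[mask]
    if out.empty:
        warnings.warn("subset produced an empty table", stacklevel=2)
    return out
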