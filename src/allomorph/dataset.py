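"""Species-by-trait tables of hindlimb morphometrics.

The central object is :class:`TraitTable`, a validated table of species means:
body mass (g), hindlimb length (cm), and the masses (g) of the five hindlimb
segments — thigh, shank, pes, tarsometatarsal segment ("tars"), and digits.
The pes is the distal unit comprising the tarsometatarsal segment plus digits,
so where all three are measured, ``tars + digit`` should roughly equal ``pes``.

A bundled table of 38 neognath bird species (see :func:`load_neognath`) is the
canonical instance; synthetic tables with known ground truth are produced by
:mod:`allomorph.simulate`.

All downstream regressions work on base-10 logarithms of the raw values, which
keeps power-law exponents directly readable as log-log slopes and makes
intercepts unit-dependent (g, cm as stored).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError, ValidationError

#: canonical CSV header, in order
CANONICAL_HEADER = (
    "species",
    "clade",
    "n",
    "body_mass_g",
    "hindlimb_length_cm",
    "thigh_mass_g",
    "shank_mass_g",
    "pes_mass_g",
    "tars_mass_g",
    "digit_mass_g",
)

#: canonical trait identifier -> CSV column
TRAIT_COLUMNS = {
    "body_mass": "body_mass_g",
    "hindlimb_length": "hindlimb_length_cm",
    "thigh_mass": "thigh_mass_g",
    "shank_mass": "shank_mass_g",
    "pes_mass": "pes_mass_g",
    "tars_mass": "tars_mass_g",
    "digit_mass": "digit_mass_g",
}

#: the five segment-mass traits, proximal to distal
SEGMENT_TRAITS = ("thigh_mass", "shank_mass", "pes_mass", "tars_mass", "digit_mass")

#: accepted encodings of a missing measurement
MISSING_MARKERS = ("", "NA", "--")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species-mean row of a trait table."""

    species_name: str
    clade: str
    n_specimens: int
    body_mass: float | None
    hindlimb_length: float | None
    thigh_mass: float | None
    shank_mass: float | None
    pes_mass: float | None
    tars_mass: float | None
    digit_mass: float | None


@dataclass
class TraitTable:
    """Ordered collection of species records with a provenance note.

    ``df`` holds one row per species with the canonical columns; missing
    measurements are ``NaN``. Row order is preserved throughout.
    """

    df: pd.DataFrame
    provenance: str = "unspecified"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return self.df["species"].tolist()

    @property
    def clades(self) -> list[str]:
        """Clade vocabulary of this table, in order of first appearance."""
        return list(dict.fromkeys(self.df["clade"]))

    def records(self) -> Iterator[SpeciesRecord]:
        for row in self.df.itertuples(index=False):
            yield SpeciesRecord(
                species_name=row.species,
                clade=row.clade,
                n_specimens=int(row.n),
                body_mass=_none_if_nan(row.body_mass_g),
                hindlimb_length=_none_if_nan(row.hindlimb_length_cm),
                thigh_mass=_none_if_nan(row.thigh_mass_g),
                shank_mass=_none_if_nan(row.shank_mass_g),
                pes_mass=_none_if_nan(row.pes_mass_g),
                tars_mass=_none_if_nan(row.tars_mass_g),
                digit_mass=_none_if_nan(row.digit_mass_g),
            )

    def trait(self, name: str) -> pd.Series:
        """Raw values of a canonical trait, indexed by species."""
        col = _trait_column(name)
        return pd.Series(
            self.df[col].to_numpy(), index=self.df["species"].to_numpy(), name=name
        )

    def to_csv(self, path: str | Path) -> None:
        """Write in the canonical dialect (missing values as empty fields)."""
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class VariablePair:
    """Matched log10 vectors of two traits over the species carrying both."""

    x_name: str
    y_name: str
    x: np.ndarray
    y: np.ndarray
    species: tuple[str, ...]
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.x)


def _none_if_nan(v):
    return None if pd.isna(v) else float(v)


def _trait_column(name: str) -> str:
    try:
        return TRAIT_COLUMNS[name]
    except KeyError:
        raise ValidationError(
            f"unknown trait {name!r}; canonical traits are {sorted(TRAIT_COLUMNS)}"
        ) from None


def read_trait_table(source, provenance: str | None = None) -> TraitTable:
    """Read and validate a species-by-trait CSV.

    ``source`` may be a path, a CSV string, or an open text stream. The header
    must declare exactly the ten canonical columns; missing values may be
    encoded as empty fields, ``NA`` or ``--``.

    Raises
    ------
    SchemaError
        on an empty stream, unknown columns, or missing columns.
    ValidationError
        on non-numeric or non-positive values (naming row and column) or
        duplicated species names.
    """
    if isinstance(source, (str, Path)) and not (
        isinstance(source, str) and "\n" in source
    ):
        provenance = provenance or str(source)
        handle = open(source, "r", encoding="utf-8")
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    try:
        raw = pd.read_csv(handle, dtype=str, keep_default_na=False, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError("empty input: no header found") from None
    finally:
        if isinstance(source, (str, Path)) and provenance is not None and hasattr(handle, "close"):
            handle.close()

    got = tuple(raw.columns)
    unknown = [c for c in got if c not in CANONICAL_HEADER]
    absent = [c for c in CANONICAL_HEADER if c not in got]
    if unknown or absent:
        raise SchemaError(
            f"header mismatch: unknown columns {unknown}, missing columns {absent}; "
            f"expected exactly {list(CANONICAL_HEADER)}"
        )
    raw = raw[list(CANONICAL_HEADER)]

    df = raw.copy()
    for col in CANONICAL_HEADER[2:]:
        df[col] = [_parse_value(v, row, col) for row, v in zip(raw["species"], raw[col])]
    df["n"] = df["n"].astype(int)

    dupes = df["species"][df["species"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate species names: {sorted(dupes)}")
    if (df["n"] < 1).any():
        bad = df.loc[df["n"] < 1, "species"].tolist()
        raise ValidationError(f"n_specimens must be a positive integer; offending rows: {bad}")

    _soft_check_pes(df)
    return TraitTable(df=df, provenance=provenance or "in-memory stream")


def _parse_value(value: str, row: str, col: str) -> float:
    v = value.strip()
    if v in MISSING_MARKERS:
        if col == "n":
            raise ValidationError(f"row {row!r}, column {col!r}: specimen count is required")
        return np.nan
    try:
        x = float(v)
    except ValueError:
        raise ValidationError(
            f"row {row!r}, column {col!r}: non-numeric value {value!r}"
        ) from None
    if x <= 0:
        raise ValidationError(f"row {row!r}, column {col!r}: value must be positive, got {x}")
    return x


def _soft_check_pes(df: pd.DataFrame) -> None:
    # input values are typically rounded, so tars + digit = pes only holds loosely.
    have = df[["pes_mass_g", "tars_mass_g", "digit_mass_g"]].notna().all(axis=1)
    sub = df[have]
    rel = np.abs((sub["tars_mass_g"] + sub["digit_mass_g"]) - sub["pes_mass_g"]) / sub[
        "pes_mass_g"
    ]
    bad = sub.loc[rel > 0.10, "species"].tolist()
    if bad:
        warnings.warn(
            f"tars + digit mass deviates from pes mass by >10% for: {bad}",
            UserWarning,
            stacklevel=3,
        )


def pair_complete(table: TraitTable, x_name: str, y_name: str, label: str = "") -> VariablePair:
    """Matched, log10-transformed vectors of two traits.

    Species missing either trait are dropped; at least 3 complete species are
    required for any downstream regression.
    """
    xcol, ycol = _trait_column(x_name), _trait_column(y_name)
    sub = table.df[["species", xcol, ycol]].dropna()
    if len(sub) < 3:
        raise InsufficientDataError(
            f"only {len(sub)} species have both {x_name} and {y_name}; need >= 3"
        )
    return VariablePair(
        x_name=x_name,
        y_name=y_name,
        x=np.log10(sub[xcol].to_numpy(float)),
        y=np.log10(sub[ycol].to_numpy(float)),
        species=tuple(sub["species"]),
        label=label or y_name,
    )


def subset_clade(table: TraitTable, clade: str) -> TraitTable:
    """Restrict a table to one clade, preserving row order."""
    known = table.clades
    if clade not in known:
        raise ValidationError(f"unknown clade {clade!r}; known clades: {known}")
    sub = table.df[table.df["clade"] == clade].reset_index(drop=True)
    return TraitTable(df=sub, provenance=f"{table.provenance} [clade={clade}]")


def load_neognath() -> TraitTable:
    """The bundled 38-species neognath hindlimb table (species means).

    Body mass in grams, hindlimb length in centimeters, segment masses in
    grams; ``--`` entries in the source are missing-not-measured.
    """
    path = resources.files("allomorph.data") / "neognath_hindlimbs.csv"
    with resources.as_file(path) as p:
        return read_trait_table(p, provenance="bundled neognath hindlimb table")
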