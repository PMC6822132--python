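"""Checklist and attribute-table input, and binary incidence matrices.

The central object here is the :class:`IncidenceMatrix`: a binary
area-by-species presence/absence table for a single survey period.
Checklists arrive as long-format delimited text (one record per
species-in-area observation); attribute tables carry per-species labels
(taxonomy, native/introduced origin, three ecological-type axes, red-list
category) that drive subsetting and loss summaries downstream.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PERIODS = ("historical", "current")

ORIGINS = ("native", "introduced")
LIFE_HABITS = ("migration", "settlement", "mountain_stream")
FEEDINGS = ("carnivorous", "herbivorous", "omnivorous")
WATER_LAYERS = ("upper", "lower", "demersal")
RED_LIST = ("CR", "EN", "VU", "NT", "LC", "DD", "NE")
ECOTYPE_AXES = ("life_habit", "feeding", "water_layer")

#: First survey year assigned to the current period. Records from the
#: boundary year itself fall in the current period.
PERIOD_BOUNDARY_YEAR = 2000


class SchemaError(ValueError):
    """A mandatory column is missing or an attribute value is invalid."""


class RecordError(ValueError):
    """One or more checklist rows could not be interpreted."""


def normalize_name(name: str) -> str:
    """Trim and collapse internal whitespace; case is preserved."""
    return " ".join(str(name).split())


def period_from_year(year: int) -> str:
    """Map a survey year to a period label.

    Years before the boundary (2000) are historical; the boundary year and
    later are current.
    """
    return "current" if int(year) >= PERIOD_BOUNDARY_YEAR else "historical"


_YEAR_RE = re.compile(r"\b(1[89]\d{2}|20\d{2})\b")


def parse_period(value: object) -> str:
    """Interpret a raw period cell.

    Accepts the two period labels (case-insensitive), a bare year, or free
    text containing a recognizable 4-digit year (e.g. ``"2005 survey"``).
    """
    text = str(value).strip()
    low = text.lower()
    if low in PERIODS:
        return low
    m = _YEAR_RE.search(text)
    if m:
        return period_from_year(int(m.group(1)))
    raise ValueError(f"cannot interpret period value {text!r}")


@dataclass(frozen=True)
class ChecklistRecord:
    """One species-in-area observation for one period."""

    species: str
    area: str
    period: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species name empty after normalization")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")


DEFAULT_SCHEMA = {
    "species": "species",
    "area": "area",
    "period": "period",
    "year": "year",
    "source": "source",
}


def read_checklist(
    stream,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[ChecklistRecord]:
    """Read a long-format checklist from a path, file object or string buffer.

    ``schema`` maps the logical column names (``species``, ``area``,
    ``period``, optionally ``year`` and ``source``) to the file's header
    names. The delimiter is sniffed unless given. When the period column is
    absent, a ``year`` column is required and mapped through
    :func:`period_from_year`. Unknown extra columns are ignored.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    if isinstance(stream, (str, Path)) and not (
        isinstance(stream, str) and "\n" in stream
    ):
        df = pd.read_csv(stream, sep=delimiter, engine="python", dtype=str)
    else:
        buf = io.StringIO(stream) if isinstance(stream, str) else stream
        df = pd.read_csv(buf, sep=delimiter, engine="python", dtype=str)

    for logical in ("species", "area"):
        if colmap[logical] not in df.columns:
            raise SchemaError(f"missing mandatory column {colmap[logical]!r}")
    has_period = colmap["period"] in df.columns
    has_year = colmap["year"] in df.columns
    if not has_period and not has_year:
        raise SchemaError(
            f"missing mandatory column {colmap['period']!r} (or a {colmap['year']!r} column)"
        )

    records: list[ChecklistRecord] = []
    bad_rows: list[str] = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, after the header
        species = normalize_name(row[colmap["species"]] if pd.notna(row[colmap["species"]]) else "")
        area = normalize_name(row[colmap["area"]] if pd.notna(row[colmap["area"]]) else "")
        if not species or not area:
            bad_rows.append(f"row {rowno}: empty species or area")
            continue
        raw_period = row[colmap["period"]] if has_period and pd.notna(row.get(colmap["period"])) else None
        if raw_period is None and has_year and pd.notna(row.get(colmap["year"])):
            raw_period = row[colmap["year"]]
        if raw_period is None:
            bad_rows.append(f"row {rowno}: no period or year")
            continue
        try:
            period = parse_period(raw_period)
        except ValueError as exc:
            bad_rows.append(f"row {rowno}: {exc}")
            continue
        source = None
        if colmap["source"] in df.columns and pd.notna(row.get(colmap["source"])):
            source = str(row[colmap["source"]])
        records.append(ChecklistRecord(species, area, period, source))

    if bad_rows:
        raise RecordError("unparseable checklist rows: " + "; ".join(bad_rows))
    if not records:
        logger.warning("checklist contained a header but no records")
    logger.info("read %d checklist records", len(records))
    return records


def normalize_names(
    records: Sequence[ChecklistRecord],
    synonym_map: Mapping[str, str] | None = None,
) -> list[ChecklistRecord]:
    """Replace species names by canonical forms from a user-supplied table.

    The map must be a single-step substitution: a mapped-to name may not
    itself be remapped (chains/cycles are configuration errors), which makes
    the operation idempotent.
    """
    if not synonym_map:
        return list(records)
    table = {normalize_name(k): normalize_name(v) for k, v in synonym_map.items()}
    for k, v in table.items():
        if not k or not v:
            raise SchemaError("synonym map contains an empty name")
        if v in table and table[v] != v:
            raise SchemaError(f"chained/cyclic synonym mapping: {k!r} -> {v!r} -> {table[v]!r}")
        if k == v:
            raise SchemaError(f"synonym maps {k!r} to itself")
    out = []
    for r in records:
        name = table.get(r.species, r.species)
        out.append(ChecklistRecord(name, r.area, r.period, r.source))
    return out


@dataclass
class IncidenceMatrix:
    """Binary area-by-species table for one period.

    ``data`` holds 0/1 integers with areas as the row index (caller-defined
    order) and species as columns (lexicographic, so the matrix is invariant
    to record order).
    """

    data: pd.DataFrame
    period: str

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate area or species labels")
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence cells must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @property
    def areas(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def presence(self, area: str) -> set[str]:
        """Set of species recorded in ``area``."""
        row = self.data.loc[area]
        return set(row.index[row.to_numpy().astype(bool)])

    def subset_species(self, species: Iterable[str]) -> "IncidenceMatrix":
        keep = [s for s in self.species if s in set(species)]
        return IncidenceMatrix(self.data[keep].copy(), self.period)

    def to_records(self) -> list[ChecklistRecord]:
        out = []
        for area in self.areas:
            for sp in sorted(self.presence(area)):
                out.append(ChecklistRecord(sp, area, self.period))
        return out

    def to_csv(self, path: str | Path) -> None:
        """Write the wide 0/1 table plus a JSON sidecar with the ordering."""
        path = Path(path)
        self.data.to_csv(path, index_label="area")
        sidecar = {
            "period": self.period,
            "areas": self.areas,
            "species": self.species,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "IncidenceMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="area")
        meta = json.loads(path.with_suffix(".json").read_text())
        df = df.loc[meta["areas"], meta["species"]]
        return cls(df, meta["period"])


def build_incidence(
    records: Sequence[ChecklistRecord],
    period: str,
    areas: Sequence[str],
) -> IncidenceMatrix:
    """Collapse checklist records for one period into a presence/absence table.

    Duplicate records collapse to a single presence; the species axis is the
    lexicographically sorted union of species seen in the period.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}")
    areas = list(areas)
    if len(set(areas)) != len(areas):
        raise ValueError("duplicate area labels")
    sel = [r for r in records if r.period == period]
    unknown = sorted({r.area for r in sel} - set(areas))
    if unknown:
        raise RecordError(f"records reference unknown areas: {unknown}")
    species = sorted({r.species for r in sel})
    if not species:
        logger.warning("no records for period %r: empty incidence matrix", period)
    df = pd.DataFrame(0, index=pd.Index(areas, name="area"), columns=species, dtype=np.int8)
    for r in sel:
        df.at[r.area, r.species] = 1
    return IncidenceMatrix(df, period)


class SpeciesAttributes:
    """Per-species labels: taxonomy, origin, ecotype axes, red-list class.

    Wraps a species-indexed DataFrame with columns ``order``, ``family``,
    ``origin``, ``life_habit``, ``feeding``, ``water_layer``, ``red_list``.
    Enum spellings are accepted case-insensitively; unknown/blank ecotype
    cells are kept as missing and the species is excluded from ecotype
    summaries. Species missing from the table entirely are treated as native
    with unknown ecotypes by the consumers of this class.
    """

    _ENUMS = {
        "origin": ORIGINS,
        "life_habit": LIFE_HABITS,
        "feeding": FEEDINGS,
        "water_layer": WATER_LAYERS,
        "red_list": RED_LIST,
    }

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "species" in df.columns:
            df["species"] = df["species"].map(normalize_name)
            df = df.set_index("species")
        df.index = [normalize_name(s) for s in df.index]
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()])
            raise SchemaError(f"duplicate species in attribute table: {dups}")
        for col, allowed in self._ENUMS.items():
            if col not in df.columns:
                df[col] = pd.NA
                continue
            norm = df[col].map(self._normalize_enum(allowed, col))
            df[col] = norm
        for col in ("order", "family"):
            if col not in df.columns:
                df[col] = pd.NA
        self.table = df

    @staticmethod
    def _normalize_enum(allowed: tuple[str, ...], col: str):
        lookup = {a.lower(): a for a in allowed}
        # accept a few common spellings from field tables
        aliases = {
            "mountain stream": "mountain_stream",
            "mountain streams": "mountain_stream",
            "resident": "settlement",
            "upper layer": "upper",
            "lower layer": "lower",
        }

        def norm(value):
            if pd.isna(value) or str(value).strip() == "":
                return pd.NA
            key = str(value).strip().lower()
            key = aliases.get(key, key)
            if key not in lookup:
                raise SchemaError(f"invalid {col} value {value!r}")
            return lookup[key]

        return norm

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesAttributes":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="species")

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    def origin(self, species: str) -> str:
        """Origin label; species absent from the table default to native."""
        if species in self.table.index:
            val = self.table.at[species, "origin"]
            if pd.notna(val):
                return val
        return "native"

    def natives(self, species: Iterable[str]) -> set[str]:
        return {s for s in species if self.origin(s) == "native"}

    def introduced(self, species: Iterable[str]) -> set[str]:
        return {s for s in species if self.origin(s) == "introduced"}

    def category(self, species: str, axis: str):
        """Ecotype category of a species on one axis, or missing."""
        if axis not in ECOTYPE_AXES:
            raise ValueError(f"axis must be one of {ECOTYPE_AXES}")
        if species not in self.table.index:
            return pd.NA
        return self.table.at[species, axis]

    def with_category(self, axis: str, category: str) -> set[str]:
        col = self.table[axis]
        return set(self.table.index[col == category])

    def family_members(self, family: str) -> set[str]:
        return set(self.table.index[self.table["family"] == family])

    def red_list_class(self, species: str):
        if species not in self.table.index:
            return pd.NA
        return self.table.at[species, "red_list"]
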