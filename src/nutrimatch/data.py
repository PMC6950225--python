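"""Food-table, link-table, and match-output I/O.

Flat CSV/TSV tables are the interchange format: one row per food, a
``food_id`` column, free-text ``name``/``description`` columns, and one
column per nutrient of the shared panel (values per 100 g edible portion).
The delimiter (comma or tab) is sniffed from the header line; commas inside
quoted description fields follow RFC-4180 quoting.  Lines starting with
``#`` are provenance headers and are skipped.

Missing optional fields (``lactose_g``, ``year``, ``dairy_servings``) are
encoded as empty cells, never as 0 — a recorded 0 g of lactose is the
meaningful lactose-free class.  ``food_id`` is an opaque string; leading
zeros are preserved.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "IntegrityError",
    "ParseError",
    "NutrientSchema",
    "FoodRecord",
    "FoodDatabase",
    "GroundTruthLink",
    "MatchEntry",
    "MatchResult",
    "default_schema",
    "read_food_table",
    "write_food_table",
    "read_links",
    "write_matches",
    "read_matches",
]


class SchemaError(ValueError):
    """A required column is missing or the schema is inconsistent."""


class IntegrityError(ValueError):
    """Duplicate identifiers or cross-table inconsistencies."""


class ParseError(ValueError):
    """A cell could not be parsed as its declared type."""


#: The 62 shared nutrient identifiers (FNDDS/ASA24-style abbreviations),
#: per 100 g edible portion.  Order is significant and fixed for a run.
DEFAULT_NUTRIENT_NAMES: tuple[str, ...] = (
    "KCAL", "PROT", "TFAT", "CARB", "MOIS", "ALC", "CAFF", "THEO",
    "SUGR", "FIBE", "CALC", "IRON", "MAGN", "PHOS", "POTA", "SODI",
    "ZINC", "COPP", "SELE", "VC", "VB1", "VB2", "NIAC", "VB6",
    "FOLA", "FA", "FF", "FDFE", "VB12", "VARA", "RET", "BCAR",
    "ACAR", "CRYP", "LYCO", "LZ", "ATOC", "VK", "CHOLE", "SFAT",
    "S040", "S060", "S080", "S100", "S120", "S140", "S160", "S180",
    "MFAT", "M161", "M181", "M201", "M221", "PFAT", "P182", "P183",
    "P184", "P204", "P205", "P225", "P226", "CHOLN",
)

_UNIT_OVERRIDES = {
    "KCAL": "kcal", "SELE": "ug", "VB12": "ug", "FOLA": "ug", "FA": "ug",
    "FF": "ug", "FDFE": "ug", "VARA": "ug", "RET": "ug", "BCAR": "ug",
    "ACAR": "ug", "CRYP": "ug", "LYCO": "ug", "LZ": "ug", "VK": "ug",
    "CALC": "mg", "IRON": "mg", "MAGN": "mg", "PHOS": "mg", "POTA": "mg",
    "SODI": "mg", "ZINC": "mg", "COPP": "mg", "VC": "mg", "VB1": "mg",
    "VB2": "mg", "NIAC": "mg", "VB6": "mg", "ATOC": "mg", "CHOLE": "mg",
    "CAFF": "mg", "THEO": "mg", "CHOLN": "mg",
}


@dataclass(frozen=True)
class NutrientSchema:
    """Ordered nutrient panel shared by the two databases.

    The default panel has 62 entries; an optional extra numeric feature
    (the recall-version year) may be appended for prediction, never for
    matching.
    """

    names: tuple[str, ...]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise SchemaError("schema must name at least one nutrient")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("nutrient names must be unique")
        if any(not n for n in self.names):
            raise SchemaError("nutrient names must be non-empty")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_schema() -> NutrientSchema:
    """The shared 62-nutrient panel with per-100 g units."""
    units = {n: _UNIT_OVERRIDES.get(n, "g") for n in DEFAULT_NUTRIENT_NAMES}
    return NutrientSchema(names=DEFAULT_NUTRIENT_NAMES, units=units)


@dataclass
class FoodRecord:
    """One food: identifiers, free text, and the shared nutrient vector."""

    food_id: str
    source: str  # {"query_db", "target_db", "synthetic"}
    name: str
    description: str
    nutrients: np.ndarray  # aligned to schema, per 100 g, each >= 0
    year: str | None = None
    lactose_g: float | None = None
    dairy_servings: float | None = None
    is_branded: bool = False
    is_drymix: bool = False
    confidence: str | None = None  # {"high", "medium", "low"}

    def validate(self, schema: NutrientSchema) -> None:
        nut = np.asarray(self.nutrients, dtype=float)
        if nut.shape != (len(schema),):
            raise SchemaError(
                f"food {self.food_id!r}: nutrient vector length {nut.shape} "
                f"does not match schema length {len(schema)}"
            )
        if not np.all(np.isfinite(nut)):
            raise ParseError(f"food {self.food_id!r}: non-finite nutrient value")
        if np.any(nut < 0):
            bad = schema.names[int(np.argmin(nut))]
            raise ParseError(
                f"food {self.food_id!r}: negative nutrient value for {bad!r}"
            )
        if self.lactose_g is not None:
            if not math.isfinite(self.lactose_g) or self.lactose_g < 0:
                raise ParseError(
                    f"food {self.food_id!r}: lactose_g must be finite and >= 0"
                )


@dataclass
class FoodDatabase:
    """A validated collection of records sharing one nutrient schema."""

    schema: NutrientSchema
    records: list[FoodRecord]
    source: str = "query_db"

    def __post_init__(self) -> None:
        self.index: dict[str, int] = {}
        for pos, rec in enumerate(self.records):
            if rec.food_id in self.index:
                raise IntegrityError(f"duplicate food_id {rec.food_id!r}")
            self.index[rec.food_id] = pos
            rec.validate(self.schema)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, food_id: str) -> FoodRecord:
        return self.records[self.index[food_id]]

    @property
    def ids(self) -> list[str]:
        return [r.food_id for r in self.records]

    @property
    def descriptions(self) -> list[str]:
        return [r.description for r in self.records]

    def nutrient_matrix(self) -> np.ndarray:
        """Records-by-nutrients matrix aligned to the schema order."""
        return np.asarray([r.nutrients for r in self.records], dtype=float)

    def lactose_values(self) -> np.ndarray:
        """Lactose per record; NaN where not recorded."""
        return np.asarray(
            [np.nan if r.lactose_g is None else r.lactose_g for r in self.records]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        rows["food_id"] = self.ids
        rows["name"] = [r.name for r in self.records]
        rows["description"] = self.descriptions
        nut = self.nutrient_matrix()
        for j, n in enumerate(self.schema.names):
            rows[n] = nut[:, j]
        rows["year"] = [r.year if r.year is not None else "" for r in self.records]
        rows["lactose_g"] = [
            "" if r.lactose_g is None else repr(float(r.lactose_g))
            for r in self.records
        ]
        rows["dairy_servings"] = [
            "" if r.dairy_servings is None else repr(float(r.dairy_servings))
            for r in self.records
        ]
        rows["is_branded"] = [int(r.is_branded) for r in self.records]
        rows["is_drymix"] = [int(r.is_drymix) for r in self.records]
        rows["confidence"] = [
            r.confidence if r.confidence is not None else "" for r in self.records
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroundTruthLink:
    """A known query-to-target correspondence; a query may have several."""

    query_id: str
    target_id: str


@dataclass
class MatchEntry:
    target_id: str
    score: float
    lactose_g: float  # NaN when the target carries no lactose value
    description: str = ""


@dataclass
class MatchResult:
    """Ranked top-k matches for one query, scores non-increasing."""

    query_id: str
    ranked: list[MatchEntry]

    def __post_init__(self) -> None:
        ids = [e.target_id for e in self.ranked]
        if len(set(ids)) != len(ids):
            raise IntegrityError(
                f"query {self.query_id!r}: duplicate target ids in ranked list"
            )
        scores = [e.score for e in self.ranked]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise IntegrityError(
                f"query {self.query_id!r}: scores must be non-increasing"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_sep(path: str) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") > line.count(",") else ","
    return ","


def _opt_float(cell, what: str, row: int) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ParseError(f"row {row}: non-numeric {what} value {s!r}") from exc


def read_food_table(
    path: str,
    schema: NutrientSchema | None = None,
    role: str = "query_db",
) -> FoodDatabase:
    """Read and validate a food table.

    Raises :class:`SchemaError` when a required column is absent (naming
    it), :class:`IntegrityError` on duplicate ``food_id``, and
    :class:`ParseError` (with the offending row number) on a non-numeric
    nutrient cell.  Rows are never silently dropped.
    """
    if schema is None:
        schema = default_schema()
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    for col in ("food_id", "description", *schema.names):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    records: list[FoodRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        nut = np.empty(len(schema))
        for j, n in enumerate(schema.names):
            cell = str(row[n]).strip()
            try:
                nut[j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"row {i + 2}: non-numeric nutrient cell {cell!r} "
                    f"in column {n!r}"
                ) from exc
        rec = FoodRecord(
            food_id=str(row["food_id"]).strip(),
            source=role,
            name=str(row.get("name", "") or ""),
            description=str(row["description"]),
            nutrients=nut,
            year=(str(row["year"]).strip() or None) if "year" in row else None,
            lactose_g=_opt_float(row.get("lactose_g"), "lactose_g", i + 2),
            dairy_servings=_opt_float(
                row.get("dairy_servings"), "dairy_servings", i + 2
            ),
            is_branded=str(row.get("is_branded", "0")).strip() in ("1", "True", "true"),
            is_drymix=str(row.get("is_drymix", "0")).strip() in ("1", "True", "true"),
            confidence=(str(row["confidence"]).strip() or None)
            if "confidence" in row
            else None,
        )
        records.append(rec)
    return FoodDatabase(schema=schema, records=records, source=role)


def write_food_table(path: str, db: FoodDatabase, header_lines: list[str] | None = None) -> None:
    """Write a food table; round-trips ids, descriptions, and nutrients."""
    df = db.to_dataframe()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, quoting=csv.QUOTE_MINIMAL, float_format="%.12g")


def read_links(path: str) -> list[GroundTruthLink]:
    """Read a two-column (query_id, target_id) link table.

    Multiplicity is preserved: a query linked to several targets yields
    one link per row.  An empty file yields an empty list with a warning;
    a row with the wrong number of columns is a :class:`ParseError`.
    """
    links: list[GroundTruthLink] = []
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [
            r
            for r in csv.reader(fh)
            if r and not (r[0].startswith("#"))
        ]
    if not rows:
        logger.warning("link table %s is empty", path)
        return links
    start = 1 if rows[0][:2] == ["query_id", "target_id"] else 0
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) != 2:
            raise ParseError(f"link row {i}: expected 2 columns, got {len(row)}")
        links.append(GroundTruthLink(query_id=row[0].strip(), target_id=row[1].strip()))
    return links


def write_links(path: str, links: list[GroundTruthLink]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["query_id", "target_id"])
        for ln in links:
            w.writerow([ln.query_id, ln.target_id])


_MATCH_COLUMNS = ["query_id", "rank", "target_id", "target_description", "score", "lactose_g"]


def write_matches(
    path: str, results: list[MatchResult], header_lines: list[str] | None = None
) -> None:
    """Write match results: one row per (query, rank), query order then rank.

    Scores and lactose are written with full float precision so a
    write-then-read round trip is exact to well past 12 significant digits.
    """
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(_MATCH_COLUMNS)
    for res in results:
        for rank, entry in enumerate(res.ranked, start=1):
            w.writerow(
                [
                    res.query_id,
                    rank,
                    entry.target_id,
                    entry.description,
                    repr(float(entry.score)),
                    "" if math.isnan(entry.lactose_g) else repr(float(entry.lactose_g)),
                ]
            )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(buf.getvalue())


def read_matches(path: str) -> list[MatchResult]:
    """Read a match table written by :func:`write_matches`."""
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows or rows[0] != _MATCH_COLUMNS:
        raise SchemaError(f"{path}: not a match table (bad header)")
    by_query: dict[str, list[MatchEntry]] = {}
    order: list[str] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(_MATCH_COLUMNS):
            raise ParseError(f"match row {i}: expected {len(_MATCH_COLUMNS)} columns")
        qid, _rank, tid, desc, score, lact = row
        if qid not in by_query:
            by_query[qid] = []
            order.append(qid)
        by_query[qid].append(
            MatchEntry(
                target_id=tid,
                score=float(score),
                lactose_g=float(lact) if lact.strip() else float("nan"),
                description=desc,
            )
        )
    return [MatchResult(query_id=q, ranked=by_query[q]) for q in order]
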