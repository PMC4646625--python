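"""Hierarchical census tables of paired farm/population frequency distributions.

The U.S. Census of Agriculture reports, for each administrative unit (the
nation, each state, each county), the number of farms and the total livestock
population cross-classified into seven farm-size bins.  Farm counts are never
confidential and are always published; population cells and totals may be
redacted ("(D)" in NASS publications) where they could reveal an individual
operation.  This module holds the data model, the file format, bound
arithmetic for redacted cells, and structural validation.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

__all__ = [
    "REDACTED",
    "BIN_BOUNDS",
    "N_BINS",
    "BinSchema",
    "Level",
    "UnitRecord",
    "CensusTable",
    "Violation",
    "ParseError",
    "InfeasibleError",
    "cell_bounds",
    "read_census",
    "write_census",
    "validate",
    "national_2012_swine",
]


class _Redacted:
    """Singleton tag for a withheld population cell."""

    _instance: Optional["_Redacted"] = None

    def __new__(cls) -> "_Redacted":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "REDACTED"


REDACTED = _Redacted()
SENTINEL = "(D)"

Cell = Union[int, _Redacted]

#: Seven farm-size classes (head per farm); the last is unbounded above.
BIN_BOUNDS: tuple[tuple[int, Optional[int]], ...] = (
    (1, 24),
    (25, 49),
    (50, 99),
    (100, 199),
    (200, 499),
    (500, 999),
    (1000, None),
)
N_BINS = len(BIN_BOUNDS)


@dataclass(frozen=True)
class BinSchema:
    """Ordered population-size bins; disjoint, contiguous, ascending, last unbounded."""

    bins: tuple[tuple[int, Optional[int]], ...] = BIN_BOUNDS

    def __post_init__(self) -> None:
        bs = self.bins
        if not bs or bs[-1][1] is not None:
            raise ValueError("last bin must be unbounded")
        for (lo, hi), (nlo, _) in zip(bs[:-1], bs[1:]):
            if hi is None or hi < lo or nlo != hi + 1:
                raise ValueError("bins must be disjoint, contiguous and ascending")


class Level(str, enum.Enum):
    NATIONAL = "national"
    STATE = "state"
    COUNTY = "county"


class ParseError(ValueError):
    """Malformed census file (bad row, unknown level, orphan parent)."""


class InfeasibleError(ValueError):
    """Published values admit no feasible completion."""


@dataclass
class UnitRecord:
    """One administrative unit's paired farm/population frequency distribution.

    ``farm_counts`` are always concrete (farm counts are public); ``pop_cells``
    and ``pop_total`` entries may be :data:`REDACTED`.
    """

    unit_id: str
    level: Level
    parent_id: Optional[str]
    farm_counts: tuple[int, ...]
    pop_cells: tuple[Cell, ...]
    pop_total: Cell

    def __post_init__(self) -> None:
        if len(self.farm_counts) != N_BINS or len(self.pop_cells) != N_BINS:
            raise ValueError("expected exactly %d bins" % N_BINS)
        if any(n < 0 for n in self.farm_counts):
            raise ValueError("negative farm count in %s" % self.unit_id)

    @property
    def n_farms(self) -> int:
        return sum(self.farm_counts)

    @property
    def complete(self) -> bool:
        """True when no population entry is redacted."""
        return self.pop_total is not REDACTED and all(
            c is not REDACTED for c in self.pop_cells
        )


def cell_bounds(rec: UnitRecord, b: int, cap: Optional[int] = None) -> tuple[int, int]:
    """Feasible [min, max] for the population of bin ``b`` (1-based) of ``rec``.

    Multiplying the farm count by the bin's minimum and maximum farm sizes
    bounds any redacted cell.  The top bin is unbounded above, so its maximum
    is ``cap`` — the unit's known (or imputed) total population.
    """
    if not 1 <= b <= N_BINS:
        raise ValueError("bin index out of range: %r" % b)
    n = rec.farm_counts[b - 1]
    lo, hi = BIN_BOUNDS[b - 1]
    if n == 0:
        return (0, 0)
    if hi is not None:
        return (n * lo, n * hi)
    if cap is None:
        raise ValueError("cap required for the unbounded bin")
    if cap < n * lo:
        raise InfeasibleError(
            "unit %s: cap %d cannot hold %d farms of >=%d head"
            % (rec.unit_id, cap, n, lo)
        )
    return (n * lo, cap)


# ---------------------------------------------------------------------------
# I/O

_HEADER = (
    ["unit_id", "level", "parent_id"]
    + ["nfarms_b%d" % b for b in range(1, N_BINS + 1)]
    + ["pop_b%d" % b for b in range(1, N_BINS + 1)]
    + ["pop_total"]
)


def _parse_cell(tok: str, where: str) -> Cell:
    tok = tok.strip()
    if tok == SENTINEL:
        return REDACTED
    try:
        v = int(tok.replace(",", ""))
    except ValueError:
        raise ParseError("%s: not an integer or %r: %r" % (where, SENTINEL, tok))
    if v < 0:
        raise ParseError("%s: negative population %d" % (where, v))
    return v


def read_census(path_or_buf) -> "CensusTable":
    """Read a census table from the delimited text format.

    Columns: ``unit_id,level,parent_id,nfarms_b1..b7,pop_b1..b7,pop_total``;
    redacted cells carry the ``(D)`` sentinel, the national parent_id is empty.
    """
    if hasattr(path_or_buf, "read"):
        rows = list(csv.reader(path_or_buf))
    else:
        with open(path_or_buf, newline="") as fh:
            rows = list(csv.reader(fh))
    if not rows or [c.strip() for c in rows[0]] != _HEADER:
        raise ParseError("missing or malformed header")
    units = []
    for i, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        where = "row %d" % i
        if len(row) != len(_HEADER):
            raise ParseError("%s: expected %d fields, got %d" % (where, len(_HEADER), len(row)))
        unit_id = row[0].strip()
        try:
            level = Level(row[1].strip())
        except ValueError:
            raise ParseError("%s: unknown level %r" % (where, row[1]))
        parent = row[2].strip() or None
        if level is not Level.NATIONAL and parent is None:
            raise ParseError("%s: %s unit %s lacks a parent" % (where, level.value, unit_id))
        try:
            farm_counts = tuple(int(c.replace(",", "")) for c in row[3 : 3 + N_BINS])
        except ValueError:
            raise ParseError("%s: farm counts must be integers (never redacted)" % where)
        pop_cells = tuple(
            _parse_cell(c, where) for c in row[3 + N_BINS : 3 + 2 * N_BINS]
        )
        pop_total = _parse_cell(row[3 + 2 * N_BINS], where)
        units.append(
            UnitRecord(unit_id, level, parent, farm_counts, pop_cells, pop_total)
        )
    return CensusTable(units)


def write_census(table: "CensusTable", path_or_buf) -> None:
    """Write a table in the same delimited format (round-trips bit-identically)."""

    def _fmt(c: Cell) -> str:
        return SENTINEL if c is REDACTED else str(c)

    def _dump(fh) -> None:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_HEADER)
        for u in table.units:
            w.writerow(
                [u.unit_id, u.level.value, u.parent_id or ""]
                + [str(n) for n in u.farm_counts]
                + [_fmt(c) for c in u.pop_cells]
                + [_fmt(u.pop_total)]
            )

    if hasattr(path_or_buf, "write"):
        _dump(path_or_buf)
    else:
        with open(path_or_buf, "w", newline="") as fh:
            _dump(fh)


# ---------------------------------------------------------------------------
# Table container + validation


@dataclass
class CensusTable:
    """A hierarchy of :class:`UnitRecord` with a shared bin schema."""

    units: list[UnitRecord]
    schema: BinSchema = field(default_factory=BinSchema)

    def __post_init__(self) -> None:
        self._index = {u.unit_id: u for u in self.units}
        if len(self._index) != len(self.units):
            raise ParseError("duplicate unit ids")
        for u in self.units:
            if u.parent_id is not None and u.parent_id not in self._index:
                raise ParseError(
                    "unit %s references missing parent %s" % (u.unit_id, u.parent_id)
                )

    def __getitem__(self, unit_id: str) -> UnitRecord:
        return self._index[unit_id]

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._index

    def at_level(self, level: Level) -> list[UnitRecord]:
        return [u for u in self.units if u.level is level]

    def children(self, unit_id: str) -> list[UnitRecord]:
        return [u for u in self.units if u.parent_id == unit_id]

    @property
    def national(self) -> UnitRecord:
        nats = self.at_level(Level.NATIONAL)
        if len(nats) != 1:
            raise ParseError("expected exactly one national unit, got %d" % len(nats))
        return nats[0]

    def with_units(self, new_units: Iterable[UnitRecord]) -> "CensusTable":
        """Copy of the table with some units replaced (matched by id)."""
        repl = {u.unit_id: u for u in new_units}
        return CensusTable(
            [repl.get(u.unit_id, u) for u in self.units], schema=self.schema
        )


@dataclass(frozen=True)
class Violation:
    unit_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "%s/%s: %s" % (self.unit_id, self.field, self.rule)


_EXPECTED_PARENT = {Level.COUNTY: Level.STATE, Level.STATE: Level.NATIONAL}


def validate(table: CensusTable) -> list[Violation]:
    """Structural checks; returns one :class:`Violation` per broken rule.

    Checks hierarchy wiring, published-cell bin bounds, the internal
    cells-sum-to-total identity, and parent/child total consistency.  All sum
    checks apply only where every participating value is published.
    """
    out: list[Violation] = []
    for u in table.units:
        want = _EXPECTED_PARENT.get(u.level)
        if want is not None:
            parent = table[u.parent_id] if u.parent_id in table else None
            if parent is None or parent.level is not want:
                out.append(Violation(u.unit_id, "parent_id", "parent must be a %s unit" % want.value))
        for b in range(1, N_BINS + 1):
            c = u.pop_cells[b - 1]
            if c is REDACTED:
                continue
            n = u.farm_counts[b - 1]
            lo, hi = BIN_BOUNDS[b - 1]
            if n == 0:
                if c != 0:
                    out.append(Violation(u.unit_id, "pop_b%d" % b, "population without farms"))
                continue
            if c < n * lo:
                out.append(
                    Violation(u.unit_id, "pop_b%d" % b, "below minimum %d" % (n * lo))
                )
            if hi is not None and c > n * hi:
                out.append(
                    Violation(u.unit_id, "pop_b%d" % b, "above maximum %d" % (n * hi))
                )
        if u.complete and sum(u.pop_cells) != u.pop_total:
            out.append(
                Violation(u.unit_id, "pop_total", "cells sum to %d, total is %d"
                          % (sum(u.pop_cells), u.pop_total))
            )
    # parent/child total consistency
    for parent in table.units:
        if parent.level is Level.COUNTY or parent.pop_total is REDACTED:
            continue
        kids = table.children(parent.unit_id)
        if not kids:
            continue
        if any(k.pop_total is REDACTED for k in kids):
            pub = sum(k.pop_total for k in kids if k.pop_total is not REDACTED)
            if pub > parent.pop_total:
                out.append(
                    Violation(parent.unit_id, "pop_total",
                              "published children exceed parent total")
                )
        elif sum(k.pop_total for k in kids) != parent.pop_total:
            out.append(
                Violation(parent.unit_id, "pop_total",
                          "children sum to %d, parent total is %d"
                          % (sum(k.pop_total for k in kids), parent.pop_total))
            )
    return out


def national_2012_swine() -> UnitRecord:
    """The published 2012 U.S. national swine distribution (farms and head).

    63,246 farms holding 66,026,785 pigs across the seven size classes; no
    cell is redacted at the national level.
    """
    return UnitRecord(
        unit_id="00",
        level=Level.NATIONAL,
        parent_id=None,
        farm_counts=(41688, 3435, 2161, 1469, 2115, 1977, 10401),
        pop_cells=(244250, 116808, 146967, 201460, 683977, 1384921, 63248402),
        pop_total=66026785,
    )
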