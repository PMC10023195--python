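"""Tabular interfaces: protein lists, numeric value tables, feature edit tables.

The required dialects are plain text: CSV, TSV and whitespace-delimited TXT
for protein lists, and fixed-header TSV for value and edit tables.  Delimiter
auto-detection is deliberately simple: tab if the first non-empty line
contains a tab, else comma if it contains a comma, else any whitespace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal

import pandas as pd

from .annotation import is_valid_accession

logger = logging.getLogger(__name__)


class TableError(ValueError):
    """Malformed or empty tabular input."""


@dataclass(frozen=True)
class ProteinQuery:
    """One requested protein: accession plus an effective display name."""

    accession: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.display_name:
            object.__setattr__(self, "display_name", self.accession)


@dataclass(frozen=True)
class ValueRow:
    accession: str
    feature_name: str
    instance_ordinal: int
    value: float


@dataclass
class ValueTable:
    """User numeric values keyed by (accession, feature name, instance ordinal)."""

    rows: list[ValueRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for r in self.rows:
            key = (r.accession, r.feature_name, r.instance_ordinal)
            if r.instance_ordinal < 1:
                raise TableError(f"instance ordinal must be >= 1: {key}")
            if key in seen:
                raise TableError(f"duplicate value-table key: {key}")
            seen.add(key)

    def lookup(self, accession: str, feature_name: str, ordinal: int) -> float | None:
        for r in self.rows:
            if (r.accession, r.feature_name, r.instance_ordinal) == (
                accession,
                feature_name,
                ordinal,
            ):
                return r.value
        return None

    def values_for(self, accession: str) -> list[float]:
        return [r.value for r in self.rows if r.accession == accession]

    @property
    def vmin(self) -> float:
        return min(r.value for r in self.rows)

    @property
    def vmax(self) -> float:
        return max(r.value for r in self.rows)


@dataclass(frozen=True)
class EditRow:
    action: Literal["add", "remove"]
    accession: str
    category: str
    name: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise TableError(f"unknown action: {self.action!r}")
        if self.start < 1 or self.length < 1:
            raise TableError(
                f"start and length must be >= 1 (got {self.start}, {self.length})"
            )


@dataclass
class EditTable:
    rows: list[EditRow] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Protein lists


def _split_line(line: str, dialect: str) -> list[str]:
    if dialect == "tsv":
        return [c.strip() for c in line.split("\t")]
    if dialect == "csv":
        return [c.strip() for c in line.split(",")]
    return line.split()


def _detect_dialect(first_line: str) -> str:
    if "\t" in first_line:
        return "tsv"
    if "," in first_line:
        return "csv"
    return "plain"


def read_protein_list(
    source: str | Path | IO[str], dialect: str = "auto"
) -> list[ProteinQuery]:
    """Read an ordered protein list (1-2 columns: accession[, display name]).

    A header row is auto-detected: a first row whose leading cell fails
    accession validation, followed by at least one row that passes, is
    dropped silently.  Other rows failing validation are skipped with a
    warning carrying the row number.  Duplicate accessions keep the first
    occurrence (omics lists often contain repeats); duplicate display names
    are disambiguated with ``_2``, ``_3`` ... suffixes.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(text.splitlines())]
    lines = [(n, ln) for n, ln in lines if ln]
    if not lines:
        raise TableError("empty list")
    if dialect == "auto":
        dialect = _detect_dialect(lines[0][1])

    parsed: list[tuple[int, list[str]]] = [(n, _split_line(ln, dialect)) for n, ln in lines]
    valid_flags = [is_valid_accession(cells[0]) for _, cells in parsed]
    if not valid_flags[0] and any(valid_flags[1:]):
        parsed = parsed[1:]
        valid_flags = valid_flags[1:]
    if not any(valid_flags):
        offending = ", ".join(f"row {n}: {cells[0]!r}" for n, cells in parsed[:5])
        raise TableError(f"no parseable accessions ({offending})")

    queries: list[ProteinQuery] = []
    seen_acc: set[str] = set()
    name_counts: dict[str, int] = {}
    for (row_no, cells), ok in zip(parsed, valid_flags):
        acc = cells[0]
        if not ok:
            logger.warning("row %d: invalid accession %r, skipped", row_no, acc)
            continue
        if acc in seen_acc:
            logger.warning("row %d: duplicate accession %s, keeping first", row_no, acc)
            continue
        seen_acc.add(acc)
        name = cells[1] if len(cells) > 1 and cells[1] else acc
        n = name_counts.get(name, 0) + 1
        name_counts[name] = n
        if n > 1:
            logger.warning("duplicate display name %r renamed to %s_%d", name, name, n)
            name = f"{name}_{n}"
        queries.append(ProteinQuery(acc, name))
    return queries


def write_protein_list(queries: Iterable[ProteinQuery], path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in queries:
            fh.write(f"{q.accession}\t{q.display_name}\n")


# ---------------------------------------------------------------------------
# Value tables


def read_value_table(path: str | Path) -> ValueTable:
    """Read a TSV with columns accession, feature, instance, value.

    The ``instance`` column may be omitted (defaults to 1).  Rows with
    non-numeric values are skipped with a warning; duplicate keys raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("accession", "feature", "value"):
        if col not in df.columns:
            raise TableError(f"value table missing required column: {col}")
    if "instance" not in df.columns:
        df["instance"] = "1"
    rows: list[ValueRow] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            value = float(row.value)
            if not math.isfinite(value):
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("row %d: non-numeric value %r, skipped", i, row.value)
            continue
        rows.append(ValueRow(row.accession, row.feature, int(row.instance), value))
    return ValueTable(rows)


def write_value_table(table: ValueTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.accession, r.feature_name, r.instance_ordinal, r.value)
            for r in table.rows
        ],
        columns=["accession", "feature", "instance", "value"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Edit tables


def read_edit_table(path: str | Path) -> EditTable:
    """Read a TSV with columns action, accession, category, name, start, length.

    Rows are validated syntactically here; semantic validation against the
    protein records happens in :func:`featmap.annotation.apply_edits`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("action", "accession", "category", "name", "start", "length"):
        if col not in df.columns:
            raise TableError(f"edit table missing required column: {col}")
    rows = [
        EditRow(
            action=row.action,
            accession=row.accession,
            category=row.category,
            name=row.name,
            start=int(row.start),
            length=int(row.length),
        )
        for row in df.itertuples(index=False)
    ]
    return EditTable(rows)


def write_edit_table(table: EditTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.action, r.accession, r.category, r.name, r.start, r.length)
            for r in table.rows
        ],
        columns=["action", "accession", "category", "name", "start", "length"],
    )
    df.to_csv(path, sep="\t", index=False)
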