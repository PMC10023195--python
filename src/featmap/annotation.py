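"""Obtain and parse UniProtKB flat-file entries into :class:`ProteinRecord` objects.

The flat-file text (ID/AC/DR/FT/SQ line types) is parsed with Biopython's
``Bio.SwissProt`` reader; this module maps the resulting record onto the small
set of drawable feature categories used throughout the package and extracts
PDB cross-references with their chain/residue coverage.

Coordinates are 1-based inclusive everywhere, matching the UniProt feature
table convention.
"""

from __future__ import annotations

import io
import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SwissProt
from Bio.SeqFeature import ExactPosition

logger = logging.getLogger(__name__)

#: FT keys drawn on the map, mapped to internal categories.  A REGION whose
#: description starts with "Disordered" additionally yields a DISORDER feature
#: (UniProt encodes intrinsic disorder that way; there is no DISORDER FT key).
FT_CATEGORIES: dict[str, str] = {
    "DOMAIN": "DOMAIN",
    "REPEAT": "REPEAT",
    "REGION": "REGION",
    "MOTIF": "MOTIF",
    "HELIX": "HELIX",
    "STRAND": "STRAND",
    "TURN": "TURN",
    "COMPBIAS": "COMPBIAS",
    "MOD_RES": "MOD_RES",
}

CATEGORIES = frozenset(FT_CATEGORIES.values()) | {"DISORDER"}

_TRAILING_COPY_RE = re.compile(r"\s+\d+$")

_ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]"
    r"|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
    r"(?:-\d+)?$"
)


def is_valid_accession(text: str) -> bool:
    """True if *text* matches the UniProtKB accession pattern.

    Accessions are 6 or 10 alphanumerics (e.g. ``P04637``, ``A0A024R161``),
    optionally suffixed with an isoform number (``P04637-2``).
    """
    return bool(_ACCESSION_RE.match(text.strip()))


def canonicalize(name: str) -> str:
    """Strip one trailing copy numeral: ``"Spectrin 9" -> "Spectrin"``.

    UniProt numbers repeat/domain copies in the description; occurrence
    counting and architecture comparison must treat all copies of a feature
    as the same name.
    """
    return _TRAILING_COPY_RE.sub("", name.strip())


class ParseError(ValueError):
    """Raised when flat-file text cannot be turned into a ProteinRecord."""


class EntryUnavailableError(RuntimeError):
    """Raised when an entry is not cached and cannot be fetched."""


class EditError(ValueError):
    """Raised when a feature edit cannot be applied to a record."""


@dataclass(frozen=True, order=True)
class Feature:
    """A typed interval on a protein sequence (1-based, inclusive ends)."""

    category: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.start}..{self.end} for {self.category} "
                f"'{self.name}'"
            )

    @property
    def canonical_name(self) -> str:
        return canonicalize(self.name)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PdbRef:
    """One PDB cross-reference with the residue ranges it covers."""

    pdb_id: str
    chain_ranges: tuple[tuple[str, int, int], ...] = ()


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    entry_name: str
    sequence: str
    features: tuple[Feature, ...] = ()
    pdb_refs: tuple[PdbRef, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_in(self, categories: Iterable[str]) -> list[Feature]:
        wanted = set(categories)
        return [f for f in self.features if f.category in wanted]


# ---------------------------------------------------------------------------
# Fetching


def _default_fetcher(accession: str) -> str:
    url = f"https://rest.uniprot.org/uniprotkb/{accession}.txt"
    with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover
        return resp.read().decode()


def fetch_entry(
    accession: str,
    cache_dir: str | Path,
    offline: bool = False,
    fetcher: Callable[[str], str] | None = None,
) -> str:
    """Return flat-file text for *accession*, reading the cache first.

    The cache holds one ``<accession>.txt`` file per entry so it can be
    pre-seeded for fully offline runs.  A live fetch (only attempted when
    ``offline`` is false) writes the cache before returning.  The retrieval
    callable is injectable so tests can count or stub network access.
    """
    if not is_valid_accession(accession):
        raise ValueError(f"not a UniProt accession: {accession!r}")
    cache_dir = Path(cache_dir)
    cached = cache_dir / f"{accession}.txt"
    if cached.exists():
        logger.debug("cache hit for %s", accession)
        return cached.read_text()
    if offline:
        raise EntryUnavailableError(f"entry unavailable offline: {accession}")
    fetch = fetcher or _default_fetcher
    try:
        text = fetch(accession)
    except urllib.error.HTTPError as exc:  # pragma: no cover - live path
        if exc.code == 404:
            raise EntryUnavailableError(
                f"obsolete or unknown accession: {accession}"
            ) from exc
        raise
    if not text.strip():
        raise EntryUnavailableError(f"obsolete or unknown accession: {accession}")
    cache_dir.mkdir(parents=True, exist_ok=True)
    cached.write_text(text)
    return text


# ---------------------------------------------------------------------------
# Parsing

_CHAIN_RANGE_RE = re.compile(r"^(?P<chains>[A-Za-z0-9/]+)=(?P<start>\d+)-(?P<end>\d+)$")


def _parse_pdb_ref(fields: Sequence[str]) -> PdbRef:
    # DR tuple: ("PDB", "1NTY", "X-ray", "2.00 A", "A=1292-1709, B=...")
    pdb_id = fields[1]
    ranges: list[tuple[str, int, int]] = []
    if len(fields) >= 5 and fields[4] not in ("-", ""):
        for part in fields[4].rstrip(".").split(","):
            m = _CHAIN_RANGE_RE.match(part.strip())
            if not m:
                continue
            start, end = int(m.group("start")), int(m.group("end"))
            for chain in m.group("chains").split("/"):
                ranges.append((chain, start, end))
    return PdbRef(pdb_id=pdb_id, chain_ranges=tuple(ranges))


def parse_entry(text: str, extra_keys: Iterable[str] = ()) -> ProteinRecord:
    """Parse one UniProtKB flat-file entry.

    FT keys outside :data:`FT_CATEGORIES` are ignored (debug-logged) unless
    listed in *extra_keys*, in which case the key itself becomes the category.
    Features with uncertain positions (``<1``, ``?..``) are skipped with a
    warning — they cannot be drawn reliably.
    """
    if "SQ   " not in text:
        raise ParseError("missing SQ block")
    try:
        sp = SwissProt.read(io.StringIO(text))
    except Exception as exc:
        raise ParseError(f"unparseable entry: {exc}") from exc
    sequence = str(sp.sequence)
    if not sequence:
        raise ParseError("missing SQ block")
    length = len(sequence)
    accession = sp.accessions[0] if sp.accessions else sp.entry_name

    extra = {k: k for k in extra_keys}
    features: list[Feature] = []
    for ft in sp.features:
        category = FT_CATEGORIES.get(ft.type, extra.get(ft.type))
        if category is None:
            logger.debug("ignoring FT key %s in %s", ft.type, accession)
            continue
        loc = ft.location
        if not isinstance(loc.start, ExactPosition) or not isinstance(
            loc.end, ExactPosition
        ):
            logger.warning(
                "skipping %s feature with uncertain position in %s", ft.type, accession
            )
            continue
        start, end = int(loc.start) + 1, int(loc.end)  # to 1-based inclusive
        name = ft.qualifiers.get("note", ft.type) if ft.qualifiers else ft.type
        if end > length or start < 1:
            raise ParseError(
                f"feature {ft.type} '{name}' at {start}..{end} exceeds "
                f"sequence length {length} in {accession}"
            )
        features.append(Feature(category, name, start, end))
        if category == "REGION" and name.startswith("Disordered"):
            features.append(Feature("DISORDER", name, start, end))

    pdb_refs = tuple(
        _parse_pdb_ref(ref) for ref in sp.cross_references if ref and ref[0] == "PDB"
    )
    return ProteinRecord(
        accession=accession,
        entry_name=sp.entry_name,
        sequence=sequence,
        features=tuple(features),
        pdb_refs=pdb_refs,
    )


# ---------------------------------------------------------------------------
# Feature-table import (generic replacement for external domain databases)


def load_feature_table(path: str | Path) -> dict[str, list[Feature]]:
    """Read a TSV of columns accession, category, name, start, end.

    Returns per-accession feature lists; apply with
    :func:`apply_feature_table`, which swaps in these DOMAIN/REPEAT
    annotations in place of the flat-file ones.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["accession", "category", "name", "start", "end"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"feature table missing required column: {col}")
    out: dict[str, list[Feature]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.accession, []).append(
            Feature(row.category, row.name, int(row.start), int(row.end))
        )
    return out


def apply_feature_table(
    records: Sequence[ProteinRecord], table: Mapping[str, Sequence[Feature]]
) -> list[ProteinRecord]:
    """Replace DOMAIN and REPEAT features of listed accessions by the table's.

    Other categories are kept unchanged.  Table rows whose interval falls
    outside the sequence are rejected with a warning.  Accessions absent from
    the table pass through untouched; an empty table is the identity.
    """
    out: list[ProteinRecord] = []
    for rec in records:
        rows = table.get(rec.accession)
        if rows is None:
            out.append(rec)
            continue
        kept = [f for f in rec.features if f.category not in ("DOMAIN", "REPEAT")]
        added: list[Feature] = []
        for f in rows:
            if f.end > rec.length:
                logger.warning(
                    "rejecting table feature %s '%s' %d..%d outside %s (len %d)",
                    f.category, f.name, f.start, f.end, rec.accession, rec.length,
                )
                continue
            added.append(f)
        out.append(replace(rec, features=tuple(kept + added)))
    return out


# ---------------------------------------------------------------------------
# Manual edits


def apply_edits(records: Sequence[ProteinRecord], edit_table) -> list[ProteinRecord]:
    """Apply add/remove feature edits (see :mod:`featmap.io_tables`).

    ``add`` appends a Feature; ``remove`` deletes the unique feature matching
    (category, name, start).  Removal with no match raises with the nearest
    candidates listed; out-of-bounds additions raise.
    """
    by_acc = {rec.accession: list(rec.features) for rec in records}
    for row in edit_table.rows:
        if row.accession not in by_acc:
            raise EditError(f"edit references unknown accession {row.accession}")
        feats = by_acc[row.accession]
        if row.action == "add":
            end = row.start + row.length - 1
            rec = next(r for r in records if r.accession == row.accession)
            if end > rec.length:
                raise EditError(
                    f"add {row.name} {row.start}..{end} exceeds length "
                    f"{rec.length} of {row.accession}"
                )
            feats.append(Feature(row.category, row.name, row.start, end))
        else:  # remove
            matches = [
                f
                for f in feats
                if f.category == row.category
                and f.name == row.name
                and f.start == row.start
            ]
            if len(matches) != 1:
                near = sorted(
                    (f for f in feats if f.category == row.category),
                    key=lambda f: abs(f.start - row.start),
                )[:3]
                hint = ", ".join(f"'{f.name}' at {f.start}..{f.end}" for f in near)
                raise EditError(
                    f"no unique {row.category} '{row.name}' at {row.start} in "
                    f"{row.accession}; nearest: {hint or 'none'}"
                )
            feats.remove(matches[0])
    return [
        replace(rec, features=tuple(by_acc[rec.accession])) for rec in records
    ]
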