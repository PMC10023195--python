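"""Row ordering: architecture similarity sorting and value-based sorting.

Between two architecture profiles, the number of shared features gives a
similarity score and the number of differing features a dissimilarity score:

    sim(A, B)    = sum over names f of min(A[f], B[f])
    dissim(A, B) = sum over names f of |A[f] - B[f]|      (L1 distance)

The default row order sorts by ascending dissimilarity to a reference
protein, then descending similarity, then input rank — so proteins sharing
feature content form contiguous blocks and the map reads as transitions
between architecture groups.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import pandas as pd

from .annotation import ProteinRecord
from .io_tables import ValueTable
from .model import ArchitectureProfile, architecture_profile

logger = logging.getLogger(__name__)


def similarity(a: ArchitectureProfile, b: ArchitectureProfile) -> int:
    """Number of shared feature instances: sum of per-name minimum counts."""
    ca, cb = a.as_counter(), b.as_counter()
    return sum(min(n, cb[name]) for name, n in ca.items() if name in cb)


def dissimilarity(a: ArchitectureProfile, b: ArchitectureProfile) -> int:
    """Number of differing feature instances: L1 distance on count vectors."""
    ca, cb = a.as_counter(), b.as_counter()
    return sum(abs(ca[name] - cb[name]) for name in set(ca) | set(cb))


def _auto_reference(profiles: Sequence[ArchitectureProfile]) -> ArchitectureProfile:
    # Largest total profile size; ties go to the earliest in input order.
    return max(profiles, key=lambda p: p.size, default=None)


def sort_by_architecture(
    records: Sequence[ProteinRecord],
    reference: str = "auto",
    mode: str = "reference",
) -> list[ProteinRecord]:
    """Order *records* by architecture similarity.

    ``mode="reference"`` (default): stable sort by the lexicographic key
    (dissimilarity to the reference ascending, similarity descending,
    original input rank).  The reference is the named accession, or with
    ``"auto"`` the protein with the largest profile.

    ``mode="chain"``: greedy nearest-neighbour chaining from the reference —
    repeatedly append the remaining protein closest (same key) to the last
    one placed.  Exploratory alternative; row order is path-dependent.
    """
    if not records:
        return []
    profiles = [architecture_profile(r) for r in records]
    if reference == "auto":
        ref = _auto_reference(profiles)
    else:
        try:
            ref = next(p for p in profiles if p.accession == reference)
        except StopIteration:
            raise KeyError(f"reference accession {reference!r} not in record set")

    if mode == "reference":
        keyed = sorted(
            range(len(records)),
            key=lambda i: (dissimilarity(profiles[i], ref), -similarity(profiles[i], ref), i),
        )
        return [records[i] for i in keyed]
    if mode == "chain":
        remaining = list(range(len(records)))
        ref_idx = profiles.index(ref)
        order = [ref_idx]
        remaining.remove(ref_idx)
        while remaining:
            last = profiles[order[-1]]
            nxt = min(
                remaining,
                key=lambda i: (dissimilarity(profiles[i], last), -similarity(profiles[i], last), i),
            )
            order.append(nxt)
            remaining.remove(nxt)
        return [records[i] for i in order]
    raise ValueError(f"unknown sort mode {mode!r}")


_AGGREGATIONS: dict[str, Callable[[list[float]], float]] = {
    "max": max,
    "min": min,
    "mean": lambda xs: sum(xs) / len(xs),
}


def sort_by_values(
    records: Sequence[ProteinRecord],
    value_table: ValueTable,
    aggregation: str = "max",
) -> list[ProteinRecord]:
    """Rank proteins by their aggregated user value, descending.

    Proteins without any value keep their relative input order and go last.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    agg = _AGGREGATIONS[aggregation]
    keyed = []
    for i, rec in enumerate(records):
        values = value_table.values_for(rec.accession)
        if values:
            keyed.append((0, -agg(values), i))
        else:
            keyed.append((1, 0.0, i))
    order = sorted(range(len(records)), key=lambda i: keyed[i])
    return [records[i] for i in order]


def pairwise_scores(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Similarity/dissimilarity for every ordered pair, for inspection/export."""
    profiles = [architecture_profile(r) for r in records]
    rows = []
    for a in profiles:
        for b in profiles:
            rows.append(
                {
                    "accession_a": a.accession,
                    "accession_b": b.accession,
                    "similarity": similarity(a, b),
                    "dissimilarity": dissimilarity(a, b),
                }
            )
    return pd.DataFrame(rows)
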