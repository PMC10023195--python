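"""Occurrence statistics and per-protein architecture profiles.

A protein's *architecture profile* is the count multiset of canonical feature
names over the four sortable categories (DOMAIN, REPEAT, REGION, MOTIF) —
"Spectrin 1" ... "Spectrin 9" all count toward one "Spectrin" key, so copy
number is what distinguishes two otherwise identical architectures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotation import Feature, ProteinRecord

#: Categories that enter profiles and the default occurrence ranking.
PROFILE_CATEGORIES = frozenset({"DOMAIN", "REPEAT", "REGION", "MOTIF"})


def _counting_keys(features: Sequence[Feature]) -> list[str]:
    """Counting key per feature: canonical name, qualified by category when the
    same canonical name appears under more than one category (rare; avoids
    silently merging, e.g., a MOTIF and a DOMAIN that share a name)."""
    cats_by_name: dict[str, set[str]] = {}
    for f in features:
        cats_by_name.setdefault(f.canonical_name, set()).add(f.category)
    keys = []
    for f in features:
        if len(cats_by_name[f.canonical_name]) > 1:
            keys.append(f"{f.canonical_name} ({f.category})")
        else:
            keys.append(f.canonical_name)
    return keys


@dataclass
class OccurrenceTable:
    """Feature occurrence counts over a whole protein set."""

    total_count: Counter = field(default_factory=Counter)
    protein_count: Counter = field(default_factory=Counter)
    per_protein: dict[str, Counter] = field(default_factory=dict)

    def ranked(self) -> list[str]:
        """Names by descending total count, ties alphabetical."""
        return sorted(self.total_count, key=lambda n: (-self.total_count[n], n))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\ttotal\tn_proteins\n")
            for name in self.ranked():
                fh.write(f"{name}\t{self.total_count[name]}\t{self.protein_count[name]}\n")


@dataclass(frozen=True)
class ArchitectureProfile:
    accession: str
    counts: tuple[tuple[str, int], ...]  # sorted (name, count) pairs

    @classmethod
    def from_counter(cls, accession: str, counts: Counter) -> "ArchitectureProfile":
        return cls(accession, tuple(sorted((n, c) for n, c in counts.items() if c > 0)))

    def as_counter(self) -> Counter:
        return Counter(dict(self.counts))

    @property
    def size(self) -> int:
        """Total number of feature instances in the profile."""
        return sum(c for _, c in self.counts)


def compute_occurrences(
    records: Sequence[ProteinRecord],
    categories: Iterable[str] = PROFILE_CATEGORIES,
) -> OccurrenceTable:
    """Count canonical feature names across *records*, per set and per protein.

    Permutation-invariant in the record list; an empty category intersection
    yields an empty table.
    """
    wanted = set(categories)
    table = OccurrenceTable()
    for rec in records:
        feats = rec.features_in(wanted)
        counter = Counter(_counting_keys(feats))
        table.per_protein[rec.accession] = counter
        for name, n in counter.items():
            table.total_count[name] += n
            table.protein_count[name] += 1
    return table


def architecture_profile(record: ProteinRecord) -> ArchitectureProfile:
    """Profile of *record* over the four sortable categories only."""
    feats = record.features_in(PROFILE_CATEGORIES)
    return ArchitectureProfile.from_counter(
        record.accession, Counter(_counting_keys(feats))
    )


def feature_ordinals(record: ProteinRecord) -> dict[tuple[str, int], Feature]:
    """Map (canonical name, 1-based instance ordinal) -> feature.

    Ordinals number same-named instances in sequence order; this is the key
    under which user value tables address individual feature copies.
    """
    out: dict[tuple[str, int], Feature] = {}
    seen: Counter = Counter()
    for f in sorted(record.features_in(PROFILE_CATEGORIES), key=lambda f: (f.start, f.end)):
        seen[f.canonical_name] += 1
        out[(f.canonical_name, seen[f.canonical_name])] = f
    return out
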