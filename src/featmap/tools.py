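"""Side utilities: per-feature FASTA extraction and regex motif search."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifMatch:
    """One regex hit on a protein sequence, 1-based inclusive coordinates."""

    accession: str
    start: int
    end: int
    matched_subsequence: str


def extract_feature_sequences(
    records: Sequence[ProteinRecord],
    canonical_name: str,
    categories: Iterable[str] | None = None,
) -> list[SeqRecord]:
    """All instances of a feature as FASTA records.

    One record per instance, header ``<accession>|<entry_name>|<name>|<start>-<end>``,
    sequence the 1-based inclusive slice; ordered by protein then position.
    """
    wanted = set(categories) if categories is not None else None
    out: list[SeqRecord] = []
    for rec in records:
        feats = [
            f
            for f in rec.features
            if f.canonical_name == canonical_name
            and (wanted is None or f.category in wanted)
        ]
        for f in sorted(feats, key=lambda f: (f.start, f.end)):
            subseq = rec.sequence[f.start - 1 : f.end]
            out.append(
                SeqRecord(
                    Seq(subseq),
                    id=f"{rec.accession}|{rec.entry_name}|{f.name}|{f.start}-{f.end}",
                    description="",
                )
            )
    if not out:
        logger.warning("no feature named %r in the record set", canonical_name)
    return out


def write_fasta(seqs: Sequence[SeqRecord], path: str | Path) -> int:
    """Write standard 60-column-wrapped FASTA; returns the record count."""
    return SeqIO.write(seqs, str(path), "fasta")


def search_motif(records: Sequence[ProteinRecord], pattern: str) -> list[MotifMatch]:
    """All regex matches on every sequence, including overlapping ones.

    The scan is position-anchored: the pattern is tried afresh at every start
    position, so overlapping motif occurrences are all reported (default
    regex iteration would skip a hit inside a previous one).  Empty matches
    are not reported.  Coordinates are 1-based inclusive.
    """
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid motif pattern {pattern!r}: {exc}") from exc
    out: list[MotifMatch] = []
    for rec in records:
        seq = rec.sequence
        for pos in range(len(seq)):
            m = rx.match(seq, pos)
            if m and m.end() > pos:
                out.append(MotifMatch(rec.accession, pos + 1, m.end(), m.group(0)))
    return out


def matches_to_tsv(matches: Sequence[MotifMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tstart\tend\tmatch\n")
        for m in matches:
            fh.write(f"{m.accession}\t{m.start}\t{m.end}\t{m.matched_subsequence}\n")
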