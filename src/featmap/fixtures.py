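"""Synthetic UniProtKB-format entries with a ground-truth manifest.

Every stage of the pipeline is testable offline: this module writes the same
flat-file dialect (ID/AC/DR/FT/SQ) that :mod:`featmap.annotation` reads, and
returns alongside it a manifest listing exactly the features the parser must
recover.  Generation is a pure function of (spec, seed).

Sequences are uniform random over the 20 amino acids — the aim is exercising
parsing, counting, sorting and drawing, not biophysical realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotation import Feature, PdbRef

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: (category, base name, typical length in residues)
DEFAULT_VOCABULARY: tuple[tuple[str, str, int], ...] = (
    ("DOMAIN", "SH3", 57),
    ("DOMAIN", "PH", 105),
    ("DOMAIN", "PDZ", 88),
    ("DOMAIN", "RhoGEF", 180),
    ("REPEAT", "Spectrin", 106),
    ("REPEAT", "WD", 40),
    ("MOTIF", "SH3-binding", 7),
    ("REGION", "Basic region", 25),
)

_MODRES_NAMES = ("Phosphoserine", "Phosphothreonine", "N6-acetyllysine")
_COMPBIAS_NAMES = ("Polar residues", "Basic and acidic residues", "Pro residues")


class FixtureError(ValueError):
    """Raised when a fixture spec cannot be realized."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic protein set."""

    n_proteins: int = 20
    length_range: tuple[int, int] = (300, 1200)
    feature_vocabulary: tuple[tuple[str, str, int], ...] = DEFAULT_VOCABULARY
    copies_range: tuple[int, int] = (0, 3)
    disorder_prob: float = 0.6
    modres_max: int = 5
    secondary_prob: float = 0.5
    compbias_prob: float = 0.4
    pdb_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise FixtureError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise FixtureError(f"bad length_range {self.length_range}")
        min_copies = self.copies_range[0]
        needed = sum(length * min_copies for _, _, length in self.feature_vocabulary)
        if needed > 0.85 * lo:
            raise FixtureError(
                f"vocabulary needs >= {needed} residues at minimum copy counts, "
                f"does not fit shortest protein ({lo} aa)"
            )


@dataclass(frozen=True)
class ManifestRow:
    accession: str
    category: str
    name: str
    start: int
    end: int


@dataclass
class FixtureManifest:
    """Ground truth for a generated set: the features the parser must emit."""

    features: list[ManifestRow] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    pdb: dict[str, list[PdbRef]] = field(default_factory=dict)

    def features_of(self, accession: str) -> list[ManifestRow]:
        return [r for r in self.features if r.accession == accession]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\tcategory\tname\tstart\tend\n")
            for r in self.features:
                fh.write(f"{r.accession}\t{r.category}\t{r.name}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# Flat-file writing


def _wrap_sequence(seq: str) -> list[str]:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append("     " + grouped)
    return lines


def make_entry_text(
    accession: str,
    entry_name: str,
    sequence: str,
    features: Sequence[Feature],
    pdb_refs: Sequence[PdbRef] = (),
) -> str:
    """Serialize one entry in the minimal flat-file dialect the parser reads."""
    n = len(sequence)
    out = [
        f"ID   {entry_name:<24}Reviewed;{n:>12} AA.",
        f"AC   {accession};",
    ]
    for ref in pdb_refs:
        if ref.chain_ranges:
            by_range: dict[tuple[int, int], list[str]] = {}
            for chain, start, end in ref.chain_ranges:
                by_range.setdefault((start, end), []).append(chain)
            spans = ", ".join(
                f"{'/'.join(chains)}={start}-{end}"
                for (start, end), chains in by_range.items()
            )
        else:
            spans = "-"
        out.append(f"DR   PDB; {ref.pdb_id}; X-ray; 2.00 A; {spans}.")
    for f in features:
        pos = str(f.start) if f.start == f.end else f"{f.start}..{f.end}"
        out.append(f"FT   {f.category:<16}{pos}")
        out.append(f'FT                   /note="{f.name}"')
    out.append(f"SQ   SEQUENCE{n:>7} AA;{n * 111:>8} MW;  0000000000000000 CRC64;")
    out.extend(_wrap_sequence(sequence))
    out.append("//")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Generation


def _place_blocks(
    rng: random.Random, blocks: list[tuple[str, str, int]], length: int
) -> list[Feature]:
    """Place blocks left-to-right without overlap, at seeded random offsets."""
    total = sum(b[2] for b in blocks)
    free = length - total
    if free < 0:
        raise FixtureError(
            f"cannot place {total} residues of features in a {length} aa protein"
        )
    offsets = sorted(rng.choices(range(free + 1), k=len(blocks)))
    placed = []
    consumed = 0
    for (category, name, size), off in zip(blocks, offsets):
        start = off + consumed + 1
        placed.append(Feature(category, name, start, start + size - 1))
        consumed += size
    return placed


def _number_copies(placed: list[Feature]) -> list[Feature]:
    """Rename multi-copy features 'Name 1', 'Name 2' ... in positional order."""
    counts: dict[tuple[str, str], int] = {}
    for f in placed:
        key = (f.category, f.name)
        counts[key] = counts.get(key, 0) + 1
    seen: dict[tuple[str, str], int] = {}
    out = []
    for f in sorted(placed, key=lambda f: f.start):
        key = (f.category, f.name)
        if counts[key] > 1:
            seen[key] = seen.get(key, 0) + 1
            out.append(Feature(f.category, f"{f.name} {seen[key]}", f.start, f.end))
        else:
            out.append(f)
    return out


def _one_protein(
    rng: random.Random, spec: FixtureSpec, accession: str, entry_name: str
) -> tuple[str, list[Feature], list[PdbRef], str]:
    length = rng.randint(*spec.length_range)
    sequence = "".join(rng.choices(AMINO_ACIDS, k=length))

    blocks: list[tuple[str, str, int]] = []
    for category, name, typical in spec.feature_vocabulary:
        copies = rng.randint(*spec.copies_range)
        blocks.extend((category, name, typical) for _ in range(copies))
    rng.shuffle(blocks)
    # Drop trailing blocks that cannot fit this particular protein.
    while sum(b[2] for b in blocks) > 0.85 * length:
        blocks.pop()
    features = _number_copies(_place_blocks(rng, blocks, length))

    if rng.random() < spec.disorder_prob:
        size = rng.randint(30, 80)
        start = rng.randint(1, max(1, length - size))
        features.append(Feature("REGION", "Disordered", start, start + size - 1))
    if rng.random() < spec.compbias_prob:
        for _ in range(rng.randint(1, 2)):
            size = rng.randint(10, 30)
            start = rng.randint(1, max(1, length - size))
            features.append(
                Feature("COMPBIAS", rng.choice(_COMPBIAS_NAMES), start, start + size - 1)
            )
    if rng.random() < spec.secondary_prob:
        pos = rng.randint(1, length // 2)
        for _ in range(rng.randint(2, 6)):
            kind = rng.choice(("HELIX", "STRAND"))
            size = rng.randint(4, 15)
            if pos + size - 1 > length:
                break
            features.append(Feature(kind, kind.capitalize(), pos, pos + size - 1))
            pos += size + rng.randint(2, 8)
    n_mod = rng.randint(0, spec.modres_max)
    if n_mod:
        for pos in sorted(rng.sample(range(1, length + 1), k=min(n_mod, length))):
            features.append(Feature("MOD_RES", rng.choice(_MODRES_NAMES), pos, pos))

    pdb_refs: list[PdbRef] = []
    if rng.random() < spec.pdb_prob:
        for _ in range(rng.randint(1, 3)):
            pdb_id = str(rng.randint(1, 9)) + "".join(
                rng.choices("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", k=3)
            )
            a = rng.randint(1, max(1, length - 50))
            b = min(length, a + rng.randint(40, 400))
            chains = ("A",) if rng.random() < 0.7 else ("A", "B")
            pdb_refs.append(PdbRef(pdb_id, tuple((c, a, b) for c in chains)))

    return sequence, features, pdb_refs, entry_name


def _manifest_rows(accession: str, features: Iterable[Feature]) -> list[ManifestRow]:
    rows = []
    for f in features:
        rows.append(ManifestRow(accession, f.category, f.name, f.start, f.end))
        if f.category == "REGION" and f.name.startswith("Disordered"):
            rows.append(ManifestRow(accession, "DISORDER", f.name, f.start, f.end))
    return rows


def generate_fixture_set(
    spec: FixtureSpec, seed: int
) -> tuple[dict[str, str], FixtureManifest]:
    """Generate flat-file texts keyed by accession, plus the ground truth.

    Accessions are synthesized as ``P`` + 5 digits from the seeded stream, so
    they exercise accession validation realistically.  DOMAIN/REPEAT/MOTIF
    placements are pairwise non-overlapping; MOD_RES, disorder, secondary
    structure and compositional-bias annotations may overlap anything, as in
    real entries.
    """
    rng = random.Random(seed)
    texts: dict[str, str] = {}
    manifest = FixtureManifest()
    accessions: set[str] = set()
    for i in range(spec.n_proteins):
        while True:
            acc = f"P{rng.randrange(100000):05d}"
            if acc not in accessions:
                accessions.add(acc)
                break
        entry_name = f"FX{i:03d}_SYNTH"
        sequence, features, pdb_refs, entry_name = _one_protein(
            rng, spec, acc, entry_name
        )
        texts[acc] = make_entry_text(acc, entry_name, sequence, features, pdb_refs)
        manifest.features.extend(_manifest_rows(acc, features))
        manifest.sequences[acc] = sequence
        manifest.pdb[acc] = list(pdb_refs)
    return texts, manifest


def seed_cache(texts: dict[str, str], cache_dir: str | Path) -> list[Path]:
    """Write each entry as ``<accession>.txt`` so fetch_entry finds it offline."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for acc, text in texts.items():
        p = cache_dir / f"{acc}.txt"
        p.write_text(text)
        paths.append(p)
    return paths
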