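"""Shared builders: hand-made records and generated fixture sets."""

from __future__ import annotations

import random

import pytest

from featmap.annotation import Feature, PdbRef, ProteinRecord
from featmap.fixtures import FixtureSpec, generate_fixture_set

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_record(
    accession: str,
    length: int = 1000,
    features: list[Feature] = (),
    pdb_refs: list[PdbRef] = (),
    entry_name: str | None = None,
    seed: int = 0,
) -> ProteinRecord:
    rng = random.Random((seed, accession).__hash__() & 0x7FFFFFFF)
    return ProteinRecord(
        accession=accession,
        entry_name=entry_name or f"{accession}_TEST",
        sequence="".join(rng.choices(AA, k=length)),
        features=tuple(features),
        pdb_refs=tuple(pdb_refs),
    )


def spectrin_repeats(n: int, start: int = 100, size: int = 106) -> list[Feature]:
    """n tandem spectrin repeats named 'Spectrin 1' ... 'Spectrin n'."""
    return [
        Feature("REPEAT", f"Spectrin {i + 1}", start + i * size, start + (i + 1) * size - 1)
        for i in range(n)
    ]


@pytest.fixture
def kalirin_like() -> ProteinRecord:
    """A record carrying nine spectrin repeats (plus an SH3 domain)."""
    feats = spectrin_repeats(9) + [Feature("DOMAIN", "SH3", 1300, 1356)]
    return make_record("P97924", length=1700, features=feats)


@pytest.fixture
def trio_like() -> ProteinRecord:
    """A homologous record annotated with only four spectrin repeats."""
    feats = spectrin_repeats(4) + [Feature("DOMAIN", "SH3", 1300, 1356)]
    return make_record("O75962", length=1700, features=feats)


@pytest.fixture(scope="session")
def small_set():
    """Eight generated proteins with their ground-truth manifest."""
    spec = FixtureSpec(n_proteins=8)
    texts, manifest = generate_fixture_set(spec, seed=11)
    return texts, manifest


@pytest.fixture(scope="session")
def small_records(small_set):
    from featmap.annotation import parse_entry

    texts, _ = small_set
    return [parse_entry(t) for t in texts.values()]
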