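# featmap

**2D feature maps of protein sets from UniProtKB flat-file annotations.**

Omics studies routinely produce lists of hundreds of proteins, and those lists
are rarely inspected *globally*: enrichment tools discard where features sit on
the sequence, and alignments only work for close homologs. An intermediate
scale of analysis is the *feature architecture* — the domains, repeats,
motifs, disordered segments, secondary-structure elements and modified
residues annotated on each sequence, and their arrangement along it.

featmap turns a list of UniProt accessions plus flat-file entries (a local
cache, so everything runs offline) into a publication-quality 2D map: one row
per protein, the x axis in residues, each feature drawn as a shaped, colored
glyph at its sequence position, with a matching legend. Around that core it
provides occurrence counting, architecture-based row sorting, seeded automatic
styling, numeric-value coloring, manual feature edits, per-feature FASTA
extraction and regex motif search.

## The architecture sort

Each protein is summarized by a count multiset over *canonical* feature names
(copy numerals stripped, so "Spectrin 1" … "Spectrin 9" all count as
`Spectrin`), restricted to the DOMAIN, REPEAT, REGION and MOTIF categories.
For two profiles $A, B$ (maps name → copy count):

$$\mathrm{sim}(A,B) = \sum_f \min(A_f, B_f), \qquad
  \mathrm{dissim}(A,B) = \sum_f |A_f - B_f|$$

i.e. the number of shared feature instances and the L1 distance between count
vectors (so $\mathrm{dissim} = |A| + |B| - 2\,\mathrm{sim}$, and dissim is a
true metric on profiles). Rows are ordered by the lexicographic key
*(dissimilarity to a reference ascending, similarity descending, input rank)*;
the reference defaults to the protein with the largest profile. Proteins with
identical architectures end up adjacent, so the map reads as transitions
between architecture groups — which makes *incomplete annotation* jump out
visually as a copy-count gap inside an otherwise homogeneous block.

## Worked example: a copy-count annotation gap

Two homologous proteins; one is annotated with nine spectrin repeats, the
other with only four. After a sequence comparison convinces you the five
"missing" repeats are real, you add them via an edit table:

```python
from featmap import (Feature, ProteinRecord, architecture_profile,
                     similarity, dissimilarity, apply_edits)
from featmap.io_tables import EditRow, EditTable

def repeats(n, start=100):
    return [Feature("REPEAT", f"Spectrin {i+1}", start + i*106, start + (i+1)*106 - 1)
            for i in range(n)]

kalirin = ProteinRecord("P97924", "KALRN_HUMAN", seq_a, tuple(repeats(9)))
trio    = ProteinRecord("O75962", "TRIO_HUMAN",  seq_b, tuple(repeats(4)))
pa, pb = architecture_profile(kalirin), architecture_profile(trio)
print("similarity   :", similarity(pa, pb))
print("dissimilarity:", dissimilarity(pa, pb))

edits = EditTable([EditRow("add", "O75962", "REPEAT", "Spectrin", 524 + i*106, 106)
                   for i in range(5)])
(trio_update,) = apply_edits([trio], edits)
print("after edits  :", dissimilarity(pa, architecture_profile(trio_update)))
```

prints

```
similarity   : 4
dissimilarity: 5
after edits  : 0
```

— four shared repeat copies, five differing ones, and distance zero once the
gap is repaired: the updated protein now sorts flush next to its homolog.

## Command line

```bash
featmap fixtures --n 6 --seed 11          # synthetic offline protein set
featmap map proteins.tsv --offline --cache-dir cache --output-dir out --pdb --modres
```

```
mapped 6 proteins (0 skipped) -> out
```

`out/` then contains `map.svg`, `map.png`, `legend.svg`, `legend.png`,
`occurrences.tsv` (feature, total count, number of proteins) and a
`manifest.json` of the run. Other subcommands: `extract` (occurrence table
only), `fasta` (all instances of a feature as FASTA), `motif` (regex scan,
overlapping matches reported). Every flag can also live in a YAML config
passed with `--config`.

With real data, point `--cache-dir` at a directory of `<accession>.txt`
UniProtKB flat files (pre-downloaded, or fetched on first use when online).

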