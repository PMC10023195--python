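# Methods

## Pipeline

A run has four stages: (1) read the protein list; (2) obtain and parse one
UniProtKB flat-file entry per accession; (3) optionally merge user inputs
(numeric value table, feature edit table, replacement feature table); (4)
count occurrences, assign styles, sort rows, and draw the map and legend.
Each stage is a plain library function; the CLI is a thin orchestration layer
over them.

## Annotation model

Coordinates are 1-based inclusive everywhere, matching the UniProt feature
table (FT) convention; a feature's length is `end − start + 1`. The FT keys
drawn on the map are DOMAIN, REPEAT, REGION, MOTIF, HELIX, STRAND, TURN,
COMPBIAS and MOD_RES (MOD_RES may be a single residue). Intrinsic disorder
has no FT key of its own: UniProt encodes it as a REGION whose description
starts with "Disordered", so parsing such a REGION additionally emits a
DISORDER feature — that is what feeds the disorder track. Other FT keys
(ZN_FING, DNA_BIND, …) are ignored by default but can be opted in via
`parse_entry(..., extra_keys=...)`; they then appear under their own key as a
category.

Flat-file reading is delegated to Biopython's SwissProt parser; this package
adds the category mapping, interval validation against the sequence length,
PDB `DR` cross-reference parsing (including `A/B=35-421` multi-chain residue
ranges), and the policy for uncertain positions: features with `<1`, `>n` or
`?` endpoints are skipped with a warning, because a glyph with an unknown
edge cannot be drawn truthfully.

**Canonical names.** Occurrence counting, sorting, styling and FASTA
extraction key features by their description with one trailing integer token
stripped ("Spectrin 9" → "Spectrin"), so repeat copies aggregate. When the
same canonical name occurs under more than one category in a record set (a
DOMAIN and a MOTIF both called "SH3", say), the instances are counted
separately as "name (category)" rather than silently merged.

**Entry cache.** One `<accession>.txt` file per entry in a user-set
directory. A cache hit never touches the network; offline mode turns a miss
into an error. The fetch callable is injectable, so any retrieval backend (or
a test stub) can stand behind the same contract.

## Architecture profiles and sorting

A profile is the count multiset of canonical names over DOMAIN, REPEAT,
REGION and MOTIF only — positional tracks (MOD_RES, secondary structure,
COMPBIAS, DISORDER) describe residue-level annotation density rather than
domain content and are excluded. Similarity is the multiset intersection
size, dissimilarity the L1 distance; the identity
`dissim = |A| + |B| − 2·sim` ties the two together, and the L1 form makes
dissimilarity a genuine metric (the test suite checks non-negativity,
identity of indiscernibles, symmetry and the triangle inequality on random
triples).

The default row order sorts by the key *(dissimilarity to reference
ascending, similarity descending, original input rank)*. Two-score sorting
against a single anchor is the simplest scheme consistent with a two-pass
"first by dissimilarity, then by similarity" reading; the reference defaults
to the largest profile (ties to the earliest in input order), which anchors
the map on the most feature-rich architecture. A greedy nearest-neighbour
chaining mode (`mode="chain"`) is available for exploration; it can follow
architecture gradients but its output is path-dependent, so it is not the
default. All ties everywhere break by input rank, making the sort stable and
re-sorting a no-op.

Value-based sorting ranks proteins by an aggregate (max, min or mean) of
their user-supplied values, descending; proteins without values keep their
relative order at the bottom.

## Styling

Features are ranked by total occurrence (ties alphabetical); the top
`max_features` (default 30 — legend legibility, configurable) each receive a
unique (shape, fill) pair from a seeded stream, the remainder share a muted
"other" style. Shapes: rounded-rect, rect, ellipse, hexagon, diamond,
chevron. Colors: a fixed 20-color qualitative palette in seeded order first,
then seeded HSV draws (s ∈ [0.55, 0.95], v ∈ [0.65, 0.95]) rejected until at
least 18° of hue away from every color already in use (after 200 failed draws
the most distant candidate is accepted — beyond ~40 features strict
separation is geometrically impossible). The default seed is 42 so one-click
runs are reproducible; passing a different seed reshuffles the look without
touching the data. The whole style map round-trips through a hand-editable
TSV (`name, shape, hex fill, hex outline`, with `*` as the "other" row).

Value coloring interpolates linearly per RGB channel between two endpoint
colors over `[vmin, vmax]` (defaults: the value table's observed range),
rounding half-up, clamping outside the range; non-finite values fall back to
the feature's default fill with a warning. Values address individual feature
copies by (canonical name, instance ordinal), ordinals numbering same-named
instances in sequence order.

## Rendering

Pixel geometry: `x(s) = left_gutter + (s − 1) · pixels_per_residue`; a
feature spanning `start..end` occupies `[x(start), x(end+1))`, so glyph width
is exactly `length · pixels_per_residue` before rounding. Defaults:
2 px/residue, 36 px row height, 16 px row gap, 150 px label gutter.

The drawing is assembled as a display list of primitives and serialized two
ways: SVG text (the source of truth) and a PNG rasterized from the same list
with Pillow. SVG coordinates are rounded half-up to 0.1 px before formatting,
which makes the byte stream independent of platform float printing; two runs
with identical inputs produce identical bytes (hash-checked in the tests).
Note one consequence: a rect's right edge is `x + width`, the sum of two
independently rounded values, so it can sit up to 0.1 px off the formula —
the geometry tests assert exactly that bound.

Z-order within a row: disorder band (translucent, behind), backbone line,
then main-category glyphs drawn longest-first (ties by start, then name) so
short features stay visible on top, then the COMPBIAS brackets, the
helix/strand bars, the PDB coverage bar (the interval union of all chain
ranges across all cross-referenced structures, adjacent intervals merged),
the MOD_RES lollipops, and the row label (right-aligned in the gutter,
ellipsis-truncated at ~7 px per character). Every glyph carries
`data-acc/cat/name/start/end` attributes, which is what makes the SVG
machine-checkable.

## Utilities

FASTA extraction emits one record per feature instance with header
`<accession>|<entry_name>|<name>|<start>-<end>` and the 1-based inclusive
slice, 60-column wrapped. The motif scanner anchors the compiled regex at
*every* start position and reports all non-empty matches, so overlapping
occurrences — common for short biological motifs — are all returned, unlike
default leftmost-nonoverlapping regex iteration; `^` still means sequence
start. Both are verified against brute-force oracles.

## Synthetic data generator

The generator emulates the *structure* of UniProtKB entries: valid synthetic
accessions (`P` + 5 digits), a vocabulary of domains/repeats/motifs placed
without overlap (copies numbered in positional order, as UniProt does),
disordered REGIONs, COMPBIAS segments, helix/strand runs, single-residue
MOD_RES sites, and PDB cross-references with chain ranges. Sequences are
uniform random over the 20 amino acids. Generation is a pure function of
(spec, seed) and every generated entry comes with a manifest of exactly the
features the parser must recover — the parser/manifest equivalence test is
the strongest correctness check in the suite.

What the generator does *not* emulate: real sequence composition,
evolutionary correlation between feature content and sequence, overlapping
domain annotations from competing databases, isoforms, or malformed entries
beyond the uncertain-position cases. Passing tests therefore demonstrate the
pipeline's correctness on well-formed annotation of realistic shape and
scale, not robustness to every artifact of live database content.

**Default scale of the checks.** Parser equivalence runs on 3 × 100 entries;
the metric property suite on 1,000 random triples; the sort oracle on all
5,040 permutations of 7 proteins; the motif oracle on 500 random sequences;
and the scale check on a 500-protein set (a realistic upper bound for a
single interactive map), which completes in a few seconds.

## Known limitations

- Live fetching uses plain HTTP GET per accession with no batching or rate
  limiting; for large online runs, pre-seeding the cache is the intended path.
- Only delimited-text inputs (CSV/TSV/TXT) are supported for lists and
  tables; spreadsheet dialects are out of scope.
- The similarity scores ignore feature *order* along the sequence: two
  proteins with the same domain counts in different arrangements are
  indistinguishable to the sort (by design — the map itself shows the
  arrangement).
- SVG text metrics are approximated (fixed per-character width) for gutter
  truncation; long labels in unusual fonts may truncate early or late.
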