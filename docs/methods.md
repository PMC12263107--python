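# Methods

## Problem and scope

pm3kit answers two PM3-curation questions about one (query variant,
publication) pair: whether the publication reports the variant at all
("variant hit"), and which partner variants the same patient carries in
trans. It operates on BioC XML full text, treats tables and prose as
independent evidence channels, and returns row- or chunk-level
provenance for every claim. It does not classify pathogenicity, count
probands across papers, parse PDFs, or ingest figures and supplementary
files.

## Variant model

Queries are coding-level HGVS: an optional transcript accession, then
`c.<pos><ref>><alt>` for substitutions, or positional `dup` / `del` /
`ins` / `delins` events. Genomic (`g.`), chromosome-prefixed, intronic
(`c.123+4`) and UTR (`c.-12`, `c.*33`) coordinates are rejected up
front: the pipeline has no transcript database, so it cannot interpret
them, and a clear error beats a silent miss. Substitutions are fully
modelled; the other kinds are handled positionally (DNA spellings and
digit tiers, no protein translation), which is exactly what is needed to
match mentions like `c.1813dup` in text or tables.

Protein-level spellings require a coding sequence. Rather than calling
an external normalisation service, augmentation accepts an optional CDS
(single-record FASTA, sequence taken as coding position 1 onward) and
translates locally with the standard genetic code: codon index
⌈pos/3⌉, reference codon read from the CDS and checked against the
variant's stated reference base (mismatch is an error, not a warning),
alternate codon translated to give `p.(Asp92Tyr)`, `p.Asp92Tyr`,
`Asp92Tyr` and `D92Y`. Stop gains are emitted in both `*` and `X`
spellings at every level, because journals use both.

Only the supplied transcript's coordinates are used; legacy or
alternative transcript numberings are not guessed.

### Match tiers

Compiled patterns come in three relaxation tiers:

* **T0 (full notation)** — every augmented spelling, tolerant of
  whitespace between tokens and of omitted parentheses, with `X`/`*`
  interchange. DNA base letters match case-insensitively (typesetting
  varies); one-letter amino-acid shorthands match case-sensitively and
  only at word boundaries, to limit false hits inside identifiers.
* **T1 (digits only)** — the coding position (and codon index, when
  protein forms exist) as a *standalone digit run*: a maximal run of
  digits not adjacent to another digit and not immediately preceded by
  `<digit>.`. This accepts `274` inside `c.274G>T` and rejects `388`
  inside `0.93884` or `rs3885`.
* **T2 (tolerant)** — as T1 for every integer within a tolerance
  (default ±2, configurable) of each position, because coordinates can
  shift slightly between reference sequences.

For ranged events the end position is matched alongside the start, since
tables sometimes cite either coordinate.

## Document handling

BioC passages whose `type` infon is `table` are lifted into structured
tables (grid as tab-separated lines, header first; short rows padded;
captions from a `caption` infon or a preceding `table_caption` passage);
`table_foot` passages are dropped. Everything else is prose. This keeps
the two channels disjoint by construction: no table cell text ever
reaches a prose chunk.

Prose passages are concatenated (blank line between sections, section
labels retained per chunk) and split into chunks of at most 1500
characters with 100-character overlap. The splitter prefers breaking at
paragraph, newline, sentence and word boundaries, searched in the later
half of the window so chunks stay near full length; with no separator
available the cut is hard and consecutive chunks share exactly the
overlap. Offsets are 0-based half-open; every character belongs to at
least one chunk.

## Retrieval

The retriever scans chunks with T0; only if fewer than
`min_chunks_before_relax` (default 1) chunks match does it rescan with
T1, then T2, keeping matches found at stricter tiers. It returns the
first `max_chunks` (default 5) matching chunks in document order — no
ranking, since position in the document is the only signal the matcher
has — and the same cap applies at every tier. Chunks whose only evidence
is a digit-tier match are flagged `position_only` so downstream answers
report them as low-confidence positional evidence.

## Table engine

All tables load into in-memory SQLite, every column as text (verbatim
round-trips; substring queries need no types). Header names are
sanitised to unique SQL identifiers (`col_<i>` for empty names,
`_2`/`_3` suffixes for duplicates) with the original header kept in
metadata; a hidden `_row` column preserves 0-based row order (rows are
displayed 1-based).

Row search runs two passes per table: a strict T0 notation scan over
every cell, then a position-guided query (template: any column contains
any position as a substring) whose fetched rows must survive the
standalone-digit post-filter before counting, with confidence
`position_only`. When a completion backend is attached it may generate
the SQL instead, but only a single read-only SELECT over that relation's
known identifiers is accepted; anything else falls back to the template.
This validation is a safety addition of this implementation.

A hit row's patient identifier is its first-column value; empty first
cells inherit the identifier from the nearest non-empty cell above (the
merged-cell convention of genotype tables). In trans candidates come
from the *contiguous* block of neighbour rows sharing that identifier —
genotype tables list biallelic rows adjacently, and contiguity prevents
leakage across families that reuse identifiers. Equal identifiers
outside the block are reported separately as low-confidence. Documents
with more than five tables are processed in order-preserving batches of
five; each table is self-contained, so batch-wise processing provably
returns the same hits as one pass (tested).

## Backends

All model interaction goes through one contract: a task
(`variant_hit`, `in_trans`, `sql_generation`, `summarize`), a context,
and the query's representation set in; a short verdict, extracted
variants, and a rationale that must be a verbatim substring of the
context out. The mock backend implements the contract with deterministic
rules — variant-hit answers yes only on a T0 match (position digits
alone never suffice); in trans extraction scans the context with generic
HGVS-like patterns (coding DNA events, long/short protein changes),
drops mentions of the query itself, and deduplicates in first-occurrence
order. The HTTP adapter sends the shipped prompt templates unmodified to
an Ollama-style server with deterministic decoding options and parses
replies into the same shape; per-task decoding settings beyond
temperature 0 are not modelled. Context is truncated to a configurable
budget (default 16 000 characters).

## Orchestration

The two channels run independently; a variant hit is their OR, since
tables and prose each contribute true positives the other misses. In
trans answers require a hit first. Table-channel candidates are
extracted by the backend from the hit row plus its neighbour block;
text-channel candidates from the retrieved chunks; the merged list is
deduplicated up to notation equivalence (same coding event ignoring
transcript, or membership of the other's augmented spellings).
`position_only` table matches are surfaced with their low-confidence
flag rather than suppressed — the curator sees the provenance and
decides. Reports are schema-versioned JSON and byte-stable under the
mock backend.

## Evaluation

Negatives for variant-hit scoring are built by seeded shuffling of the
query variants until a derangement is found in which no document
receives its own variant and no assigned variant actually matches its
document. "Matches" means a full-notation (T0) hit by default; digit-tier
collisions are allowed, since a negative only needs to be unreported,
not digit-free. A `strict` mode forbids any-tier collisions for users
who want leak-free retrieval experiments. Bounded retries guard the
impossible case (every document mentions every variant).

Variant hit uses accuracy, F1 (positive class = variant reported),
sensitivity and specificity from the confusion counts. In trans recall
is micro-averaged over truth variants (macro behind a flag); pairs with
empty truth contribute nothing, and all-empty truth yields an undefined
recall reported as `None`, never 1.0.

## Synthetic publications

The generator emulates the two places PM3 evidence actually appears:
a case-report sentence ("Patient P3 carried c.274G>T in trans with
c.35delG.") and a genotype table keyed by patient identifier, in
per-patient (allele columns side by side) or per-allele (patient
spanning adjacent rows, identifier repeated or blank) layout. Decoy
patients carry substitutions at positions kept more than 10 away from
the query and partner positions, so the planted truth is unambiguous.
`trap_decimals` plants the query position inside decimal frequencies
("0.93884"-style) in prose and in a frequency table, exercising the
post-filter. Patient-identifier styles and column-name pools are drawn
per seed from rare-disease table conventions so the engine is not tuned
to one dialect. The same spec and seed give byte-identical XML.

What the generator does **not** emulate: OCR noise, multi-gene tables,
footnote markers inside cells, split or nested headers, figures and
supplementary files, and free-text genotype descriptions ("homozygous
for the common deletion"). Perfect recovery on these fixtures therefore
demonstrates the plumbing — channel separation, matching, post-filters,
row expansion, merging — not performance on real publications, which
depends on the completion backend used.

Generated coding sequences start with ATG, contain no stop codon outside
pinned codons, and honour pinned codons exactly (conflicting pins are an
error); they are CDS fragments, so no terminal stop is appended.

## Problem sizes and numerical choices

The test suite exercises randomized properties at sizes chosen to finish
in seconds while covering the behaviour space: 100 random CDS/
substitution pairs for translation (against whole-CDS translation as the
oracle), 1000 random digit-heavy texts for the standalone-digit scanner
(against a brute-force run enumerator), and a 200-document synthetic
corpus (mixed channels, layouts, traps, 1–4 patients) for end-to-end
recovery, on which the mock pipeline must reach variant-hit accuracy 1.0
and in trans recall 1.0 with zero trap-induced false hits. Determinism
is absolute under the mock backend: no tolerances are needed anywhere;
ties in retrieval are broken by document order, and candidate
deduplication keeps the first occurrence.
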