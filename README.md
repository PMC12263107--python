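# pm3kit

Extraction of ACMG/AMP **PM3 evidence** from full-text publications.

PM3 is the ACMG/AMP moderate-evidence criterion for recessive disease: a
variant is observed *in trans* (on the other haplotype) with a known
pathogenic variant in an affected individual. Applying it means answering
two questions about a publication: *does this paper report my query
variant at all?* (the "variant hit"), and *which partner variants do the
same patients carry on the other allele?* Curators answer these by hand
today, reading case reports and genotype tables — pm3kit automates both
steps with document-level provenance, for clinical curators and for
anyone building literature-evidence pipelines.

## How it works

Given a query variant in HGVS coding notation (e.g.
`NM_004004.5:c.71G>A`) and a publication in BioC XML, the pipeline:

1. **Augments** the variant into every spelling the literature uses:
   `c.274G>T`, transcript-prefixed and bare DNA forms, and — when a
   coding sequence is supplied — the protein change `p.(Asp92Tyr)`, its
   shorthand `D92Y`, with stop codons spelled `Ter`, `*` or `X`
   interchangeably. The codon index is ⌈position/3⌉ (c.274 → codon 92).
2. **Separates tables from prose.** Tables are loaded verbatim into
   SQLite; rows carrying the variant are found by notation match or by a
   position-guided query whose results pass a digit-boundary post-filter
   (position 388 must not fire inside "frequency is 0.93884"). A hit
   row's first-column patient identifier links it to its contiguous
   neighbour rows, which supply the *in trans* candidates. More than five
   tables are processed in order-preserving batches.
3. **Retrieves prose evidence.** The text is split into 1500-character
   chunks with 100-character overlap; a variant-specific retriever
   returns at most five chunks, matching full notation first and
   relaxing to digits-only and then to a ±2 position window only when
   stricter tiers find too little.
4. **Asks a completion backend** the predefined variant-hit and in trans
   questions over the retrieved context. The bundled mock backend
   answers them with deterministic rules (exact pattern evidence, HGVS
   mention extraction), so the full pipeline runs offline; an HTTP
   adapter targets a local model server instead.

Evidence from both channels is merged (a hit in either channel counts),
deduplicated up to notation equivalence, and every answer carries a
`Table N, row M` or chunk-offset provenance item.

The evaluation module scores variant-hit detection as binary
classification (accuracy, F1, sensitivity, specificity), building
negatives by a seeded derangement that reassigns each publication a real
query variant it does not mention, and scores in trans detection by
recall against curated truth lists. A synthetic-publication generator
produces seeded BioC documents with planted mentions, genotype tables
and decimal-digit decoys, with machine-readable ground truth.

## Worked example

```python
from pm3kit import read_bioc, run_pair
from pm3kit.synth import FixtureSpec, generate_publication

spec = FixtureSpec(
    query_variant="NM_000059.4:c.7796A>G",
    in_trans_variant="c.1813dup",
    mention_channels={"text", "table"},
    table_layout="one_row_per_allele",
    seed=33,
)
xml, truth = generate_publication(spec)
report = run_pair(read_bioc(xml), "NM_000059.4:c.7796A>G")
print("variant_hit:", report["variant_hit"]["value"])
print("in_trans:", report["in_trans"]["variants"])
for item in report["in_trans"]["provenance"]:
    print(f"  {item['channel']} evidence ({item['confidence']}):",
          f"{item['table_label']}, row {item['row_index'] + 1}")
print("summary:", report["summary"])
```

prints

```
variant_hit: True
in_trans: ['c.1813dup']
  table evidence (notation): Table 1, row 6
summary: Source: Table 1, row 6 |  | c.1813dup | het
```

meaning: the query variant was found in the document (by exact
notation), the patient carrying it also carries `c.1813dup` on the other
allele, and the evidence row is row 6 of Table 1 — a per-allele genotype
table in which the partner allele sits on the patient's second row
(blank first cell, merged-cell convention, hence the empty field in the
summary line).

The same flow is available from the shell:

```bash
pm3 synth --variant "c.274G>T" --seed 7 --out fixture/
pm3 run --variant "c.274G>T" --bioc fixture/doc.xml --backend mock --out report.json
pm3 eval --bench bench.json --docs docs/ --seed 3 --out eval.json
```

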