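{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PM3 benchmark record list",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["variant", "doc_id"],
    "properties": {
      "variant": {
        "type": "string",
        "description": "Query variant in HGVS coding notation, optionally transcript-prefixed (e.g. NM_004004.5:c.71G>A)."
      },
      "doc_id": {
        "type": "string",
        "description": "PMID or PMCID of the linked publication."
      },
      "truth_in_trans": {
        "type": "array",
        "items": {"type": "string"},
        "default": [],
        "description": "Curated in trans partner variants (may be empty)."
      },
      "n_probands": {
        "type": "integer",
        "minimum": 0,
        "default": 0,
        "description": "Number of probands supporting the evidence."
      },
      "label": {
        "type": "string",
        "enum": ["positive", "negative"],
        "default": "positive"
      }
    }
  }
}
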