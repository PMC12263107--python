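[
  {
    "variant": "NM_004004.5:c.71G>A",
    "doc_id": "SYNDOC1",
    "truth_in_trans": ["c.35delG", "c.167delT"],
    "n_probands": 2,
    "label": "positive"
  },
  {
    "variant": "NM_000059.4:c.7796A>G",
    "doc_id": "SYNDOC2",
    "truth_in_trans": ["c.1813dup"],
    "n_probands": 1,
    "label": "positive"
  },
  {
    "variant": "c.274G>T",
    "doc_id": "SYNDOC3",
    "truth_in_trans": [],
    "n_probands": 1,
    "label": "positive"
  },
  {
    "variant": "c.388A>G",
    "doc_id": "SYNDOC4",
    "truth_in_trans": ["c.1000C>T"],
    "n_probands": 3,
    "label": "positive"
  },
  {
    "variant": "c.1813dup",
    "doc_id": "SYNDOC5",
    "truth_in_trans": ["c.7796A>G"],
    "n_probands": 1,
    "label": "positive"
  }
]
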