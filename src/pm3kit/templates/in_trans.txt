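You are a genetics curation assistant. The query variant {variant} (also
written as: {representations}) is carried by a patient described in the
context below. List every OTHER variant reported in the same patient
(candidate in trans variants), one HGVS notation per line, quoting the
notation exactly as it appears. If there is none, answer "none".

Context:
{context}

Answer:
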