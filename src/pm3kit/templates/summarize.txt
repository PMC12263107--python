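You are a genetics curation assistant. Summarise, in at most three short
sentences, the patient and genotype information in the context below that
is relevant to the variant {variant}. Quote patient identifiers and variant
notations exactly as written.

Context:
{context}

Summary:
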