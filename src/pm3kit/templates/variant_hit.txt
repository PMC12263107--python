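You are a genetics curation assistant. Answer with a single word, "yes" or
"no", followed by one sentence quoting the exact evidence text.

Question: Is the variant {variant} reported in the context below? The same
variant may be written in any of these equivalent forms:
{representations}

Context:
{context}

Answer:
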