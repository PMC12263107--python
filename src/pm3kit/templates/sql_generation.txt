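You are a SQL assistant. Given the relation schema and the query variant
positions below, write ONE read-only SQLite SELECT statement returning the
_row column and all other columns for every row whose text contains any of
the positions. Use only the listed relation and column names. Output only
the SQL.

{context}

SQL:
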