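"""SQLite-backed table querying for variant rows and in trans partners.

Genotype evidence in case reports usually lives in tables: one row per
patient (allele columns side by side) or one row per allele (a patient
spanning adjacent rows). Every table of a publication is loaded verbatim
into an in-memory SQLite database, all columns as text. Variant rows are
found two ways: strict notation matching with the query's compiled
patterns, and a position-guided substring query whose results are then
post-filtered so a position like 388 buried inside statistical digits
("frequency is 0.93884", "rs3885") never counts as a match.

A matched row's first-column value is taken as the patient identifier;
the contiguous block of adjacent rows sharing that identifier (empty
first cells inherit the identifier from above — the merged-cell
convention) supplies the candidate *in trans* rows. Documents with more
than ``max_per_batch`` tables are processed in order-preserving batches;
batching never changes the set of hits.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bioc import DocumentBundle, Table
from .variants import (
    RepresentationSet,
    Tier,
    compile_patterns,
    contains_standalone_digits,
)

_ROW_COL = "_row"

_SQL_FORBIDDEN = re.compile(
    r"\b(insert|update|delete|drop|create|alter|replace|attach|detach|pragma|vacuum)\b",
    re.IGNORECASE,
)
_SQL_WORD = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_SQL_KEYWORDS = {
    "select", "from", "where", "and", "or", "not", "like", "in", "is",
    "null", "as", "distinct", "order", "by", "limit", "asc", "desc",
    "instr", "lower", "upper", "cast", "text", "between", "glob",
}


@dataclass
class TableMeta:
    relation: str
    table_label: str
    header: list[str]
    columns: list[str]  # sanitized, same length as header
    n_rows: int


@dataclass(frozen=True)
class TableHit:
    table_label: str
    row_index: int  # 0-based storage index; display as row_index + 1
    row_cells: list[str]
    matched_cell_index: int
    matched_text: str
    patient_id: str
    confidence: str  # "notation" | "position_only"

    def __post_init__(self) -> None:
        assert self.matched_cell_index < len(self.row_cells)


def sanitize_headers(header: Sequence[str]) -> list[str]:
    """Header names → unique SQL-safe column names.

    Empty names become positional ``col_<i>``; duplicates get ``_2``,
    ``_3`` … suffixes; names may not start with a digit.
    """
    out: list[str] = []
    seen: dict[str, int] = {}
    for i, name in enumerate(header):
        base = re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")
        if not base:
            base = f"col_{i + 1}"
        if base[0].isdigit():
            base = "c" + base
        count = seen.get(base, 0) + 1
        seen[base] = count
        out.append(base if count == 1 else f"{base}_{count}")
    return out


class TableStore:
    """All tables of one publication in an in-memory SQLite database."""

    def __init__(self, tables: Sequence[Table]):
        self.conn = sqlite3.connect(":memory:")
        self.metas: list[TableMeta] = []
        self.tables: list[Table] = list(tables)
        for i, table in enumerate(tables):
            relation = f"table_{i + 1}"
            columns = sanitize_headers(table.header) if table.header else ["col_1"]
            col_defs = ", ".join(f'"{c}" TEXT' for c in columns)
            self.conn.execute(
                f'CREATE TABLE "{relation}" ({_ROW_COL} INTEGER, {col_defs})'
            )
            placeholders = ", ".join("?" * (len(columns) + 1))
            for ridx, row in enumerate(table.rows):
                padded = list(row[: len(columns)]) + [""] * (len(columns) - len(row))
                self.conn.execute(
                    f'INSERT INTO "{relation}" VALUES ({placeholders})',
                    [ridx, *padded],
                )
            self.metas.append(
                TableMeta(
                    relation=relation,
                    table_label=table.table_label,
                    header=list(table.header),
                    columns=columns,
                    n_rows=len(table.rows),
                )
            )
        self.conn.commit()

    @property
    def total_rows(self) -> int:
        return sum(m.n_rows for m in self.metas)

    def row_cells(self, meta: TableMeta, row_index: int) -> list[str]:
        cols = ", ".join(f'"{c}"' for c in meta.columns)
        cur = self.conn.execute(
            f'SELECT {cols} FROM "{meta.relation}" WHERE {_ROW_COL} = ?',
            (row_index,),
        )
        row = cur.fetchone()
        if row is None:
            raise KeyError(f"{meta.relation} has no row {row_index}")
        return list(row)

    def resolved_patient_ids(self, meta: TableMeta) -> list[str]:
        """First-column values with empty cells inheriting from above."""
        ids: list[str] = []
        last = ""
        for ridx in range(meta.n_rows):
            cell = self.row_cells(meta, ridx)[0].strip()
            if cell:
                last = cell
            ids.append(last)
        return ids

    def export_tsv(self, directory) -> list[str]:
        """Write each relation as a TSV file for inspection; returns paths."""
        import os

        paths = []
        os.makedirs(directory, exist_ok=True)
        for meta in self.metas:
            path = os.path.join(directory, f"{meta.relation}.tsv")
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("\t".join(meta.header or meta.columns) + "\n")
                for ridx in range(meta.n_rows):
                    fh.write("\t".join(self.row_cells(meta, ridx)) + "\n")
            paths.append(path)
        return paths


def load_tables(bundle_or_tables) -> TableStore:
    """Load a document's tables (or a plain table list) into a store."""
    if isinstance(bundle_or_tables, DocumentBundle):
        return TableStore(bundle_or_tables.tables)
    return TableStore(bundle_or_tables)


# --- position-guided SQL ---------------------------------------------------


def _template_query(relation: str, columns: Sequence[str], positions: Sequence[int]) -> str:
    clauses = [
        f"instr(\"{col}\", '{pos}') > 0" for col in columns for pos in positions
    ]
    where = " OR ".join(clauses) if clauses else "0"
    cols = ", ".join(f'"{c}"' for c in columns)
    return f'SELECT {_ROW_COL}, {cols} FROM "{relation}" WHERE {where}'


def validate_query(sql: str, relation: str, columns: Sequence[str]) -> bool:
    """Accept only a single read-only SELECT over known identifiers."""
    stripped = sql.strip().rstrip(";")
    if ";" in stripped:
        return False
    if not stripped.lower().startswith("select"):
        return False
    if _SQL_FORBIDDEN.search(stripped):
        return False
    known = {relation.lower(), _ROW_COL} | {c.lower() for c in columns}
    for word in _SQL_WORD.findall(stripped):
        w = word.lower()
        if w not in known and w not in _SQL_KEYWORDS:
            return False
    return True


def generate_position_query(
    meta: TableMeta,
    positions: Sequence[int],
    backend=None,
) -> str:
    """Build the row-finding query for one relation.

    The deterministic template selects every row whose text contains any
    query position as a substring (the digit-boundary post-filter runs
    afterwards). When a completion backend is supplied, its generated SQL
    is used instead — but only if it validates as a single read-only
    SELECT over this relation's identifiers; anything else falls back to
    the template.
    """
    if not meta.columns:
        raise ValueError(f"relation {meta.relation} has an empty schema")
    template = _template_query(meta.relation, meta.columns, positions)
    if backend is None:
        return template
    from .backends import BackendRequest  # local import to avoid a cycle

    schema_desc = (
        f"relation: {meta.relation}\ncolumns: {', '.join(meta.columns)}\n"
        f"positions: {', '.join(str(p) for p in positions)}"
    )
    answer = backend.complete(
        BackendRequest(task="sql_generation", context=schema_desc)
    )
    sql = getattr(answer, "sql", None)
    if sql and validate_query(sql, meta.relation, meta.columns):
        return sql
    return template


def position_postfilter(cell_text: str, position: int) -> bool:
    """Accept a substring-matched cell only on a standalone digit run.

    Rejects positions hiding inside longer numbers or decimal fractions,
    e.g. 388 in "frequency is 0.93884" or in "rs3885".
    """
    return contains_standalone_digits(cell_text, position)


# --- variant-row search ----------------------------------------------------


def find_variant_rows(
    store: TableStore,
    representation_set: RepresentationSet,
    backend=None,
) -> list[TableHit]:
    """All rows carrying the query variant, ordered by (table, row).

    Rows matched by full notation get ``confidence="notation"``; rows
    that only survive the position query plus digit-boundary post-filter
    get ``confidence="position_only"``.
    """
    t0 = compile_patterns(representation_set, Tier.T0_FULL)
    positions = representation_set.positions
    hits: list[TableHit] = []
    for meta in store.metas:
        patient_ids = store.resolved_patient_ids(meta)
        hit_rows: set[int] = set()
        # pass 1: strict notation match on every cell
        for ridx in range(meta.n_rows):
            cells = store.row_cells(meta, ridx)
            for cidx, cell in enumerate(cells):
                m = t0.search(cell)
                if m:
                    hits.append(
                        TableHit(
                            table_label=meta.table_label,
                            row_index=ridx,
                            row_cells=cells,
                            matched_cell_index=cidx,
                            matched_text=m.text,
                            patient_id=patient_ids[ridx],
                            confidence="notation",
                        )
                    )
                    hit_rows.add(ridx)
                    break
        # pass 2: position-guided query + post-filter for remaining rows
        sql = generate_position_query(meta, positions, backend=backend)
        for fetched in store.conn.execute(sql):
            ridx = fetched[0]
            if ridx in hit_rows:
                continue
            cells = list(fetched[1:])
            for cidx, cell in enumerate(cells):
                pos_ok = next(
                    (p for p in positions if position_postfilter(cell, p)), None
                )
                if pos_ok is not None:
                    hits.append(
                        TableHit(
                            table_label=meta.table_label,
                            row_index=ridx,
                            row_cells=cells,
                            matched_cell_index=cidx,
                            matched_text=str(pos_ok),
                            patient_id=patient_ids[ridx],
                            confidence="position_only",
                        )
                    )
                    hit_rows.add(ridx)
                    break
    order = {m.table_label: i for i, m in enumerate(store.metas)}
    hits.sort(key=lambda h: (order[h.table_label], h.row_index))
    return hits


def _meta_for_label(store: TableStore, table_label: str) -> TableMeta:
    for meta in store.metas:
        if meta.table_label == table_label:
            return meta
    raise KeyError(f"no table labelled {table_label!r} in store")


def extract_in_trans_rows(store: TableStore, hit: TableHit) -> list[TableHit]:
    """Contiguous neighbour rows sharing the hit row's patient identifier.

    Walks upward and downward from the hit row while the resolved
    first-column identifier stays equal, excluding the hit row itself —
    in per-allele genotype tables these sibling rows carry the other
    allele of the same patient.
    """
    meta = _meta_for_label(store, hit.table_label)
    ids = store.resolved_patient_ids(meta)
    if not (0 <= hit.row_index < meta.n_rows):
        raise KeyError(f"hit row {hit.row_index} outside {meta.table_label}")
    pid = ids[hit.row_index]
    rows: list[int] = []
    r = hit.row_index - 1
    while r >= 0 and ids[r] == pid:
        rows.append(r)
        r -= 1
    r = hit.row_index + 1
    while r < meta.n_rows and ids[r] == pid:
        rows.append(r)
        r += 1
    rows.sort()
    return [
        TableHit(
            table_label=meta.table_label,
            row_index=r,
            row_cells=store.row_cells(meta, r),
            matched_cell_index=0,
            matched_text=pid,
            patient_id=pid,
            confidence=hit.confidence,
        )
        for r in rows
    ]


def distant_same_id_rows(store: TableStore, hit: TableHit) -> list[TableHit]:
    """Same-identifier rows outside the contiguous block (low confidence)."""
    meta = _meta_for_label(store, hit.table_label)
    ids = store.resolved_patient_ids(meta)
    block = {h.row_index for h in extract_in_trans_rows(store, hit)}
    block.add(hit.row_index)
    return [
        TableHit(
            table_label=meta.table_label,
            row_index=r,
            row_cells=store.row_cells(meta, r),
            matched_cell_index=0,
            matched_text=ids[r],
            patient_id=ids[r],
            confidence="position_only",
        )
        for r in range(meta.n_rows)
        if ids[r] == ids[hit.row_index] and r not in block
    ]


def batch_tables(tables: Sequence[Table], max_per_batch: int = 5) -> list[list[Table]]:
    """Order-preserving greedy batches of at most ``max_per_batch`` tables."""
    if max_per_batch < 1:
        raise ValueError("max_per_batch must be >= 1")
    tables = list(tables)
    return [tables[i: i + max_per_batch] for i in range(0, len(tables), max_per_batch)]
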