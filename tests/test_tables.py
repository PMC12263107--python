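"""SQLite table store, position-guided queries, and in trans row expansion."""

import random

import pytest

from pm3kit.bioc import Table
from pm3kit.tables import (
    TableStore,
    batch_tables,
    distant_same_id_rows,
    extract_in_trans_rows,
    find_variant_rows,
    generate_position_query,
    load_tables,
    position_postfilter,
    sanitize_headers,
    validate_query,
)
from pm3kit.variants import augment_variant, parse_hgvs

from conftest import digit_run_oracle, random_digit_text


def genotype_table(rows, header=("Patient", "Allele 1", "Allele 2"),
                   label="Table 1"):
    return Table(table_label=label, caption="", header=list(header),
                 rows=[list(r) for r in rows])


@pytest.fixture
def rep():
    return augment_variant(parse_hgvs("c.274G>T"))


class TestStore:
    def test_row_conservation(self):
        t1 = genotype_table([["P1", "a", "b"]] * 3)
        t2 = genotype_table([["P2", "c", "d"]] * 4, label="Table 2")
        store = TableStore([t1, t2])
        assert len(store.metas) == 2
        assert store.total_rows == 7

    def test_header_sanitation(self):
        assert sanitize_headers(["", "Allele 1", "Allele 1"]) == [
            "col_1", "allele_1", "allele_1_2",
        ]
        assert sanitize_headers(["2nd allele"]) == ["c2nd_allele"]

    def test_cell_round_trip(self):
        cell = "c.71G>A;c.35delG"
        store = TableStore([genotype_table([["P1", cell, "wt"]])])
        assert store.row_cells(store.metas[0], 0)[1] == cell

    def test_merged_cell_id_inheritance(self):
        t = genotype_table(
            [["P1", "x", ""], ["", "y", ""], ["P2", "z", ""]],
        )
        store = TableStore([t])
        assert store.resolved_patient_ids(store.metas[0]) == ["P1", "P1", "P2"]

    def test_export_tsv(self, tmp_path):
        store = TableStore([genotype_table([["P1", "a", "b"]])])
        (path,) = store.export_tsv(tmp_path)
        lines = open(path).read().splitlines()
        assert lines == ["Patient\tAllele 1\tAllele 2", "P1\ta\tb"]


class TestPositionQuery:
    def test_template_matches_positions(self, rep):
        store = TableStore([genotype_table(
            [["P1", "c.274G>T", "wt"], ["P2", "c.100A>G", "wt"]]
        )])
        meta = store.metas[0]
        sql = generate_position_query(meta, [274, 92])
        rows = list(store.conn.execute(sql))
        assert [r[0] for r in rows] == [0]

    def test_single_column_table(self):
        store = TableStore([Table("Table 1", "", ["Variant"], [["c.71G>A"]])])
        sql = generate_position_query(store.metas[0], [71])
        assert list(store.conn.execute(sql))

    def test_write_statement_rejected(self):
        class EvilBackend:
            def complete(self, request):
                from pm3kit.backends import BackendAnswer
                return BackendAnswer(
                    verdict="n/a", sql='DROP TABLE "table_1"'
                )

        store = TableStore([genotype_table([["P1", "c.274G>T", "wt"]])])
        sql = generate_position_query(store.metas[0], [274], backend=EvilBackend())
        assert sql.lower().startswith("select")
        assert "drop" not in sql.lower()

    def test_valid_backend_query_used(self):
        class GoodBackend:
            def complete(self, request):
                from pm3kit.backends import BackendAnswer
                return BackendAnswer(
                    verdict="n/a",
                    sql=('SELECT _row, "patient", "allele_1", "allele_2" '
                         'FROM "table_1" WHERE instr("allele_1", \'274\') > 0'),
                )

        store = TableStore([genotype_table([["P1", "c.274G>T", "wt"]])])
        sql = generate_position_query(store.metas[0], [274], backend=GoodBackend())
        assert 'instr("allele_1"' in sql

    def test_validate_query_rules(self):
        cols = ["patient", "allele_1"]
        ok = 'SELECT _row, "patient" FROM "table_1" WHERE instr("allele_1", \'7\') > 0'
        assert validate_query(ok, "table_1", cols)
        assert not validate_query("SELECT * FROM other_table", "table_1", cols)
        assert not validate_query(
            "SELECT * FROM table_1; DELETE FROM table_1", "table_1", cols
        )


class TestPostfilter:
    @pytest.mark.parametrize(
        "cell,pos,accept",
        [
            ("frequency is 0.93884", 388, False),
            ("c.388A>G", 388, True),
            ("rs3885", 388, False),
            ("position 388.", 388, True),
            ("0.388", 388, False),
        ],
    )
    def test_printed_examples(self, cell, pos, accept):
        assert position_postfilter(cell, pos) is accept

    def test_oracle_equivalence_on_random_cells(self):
        """Accept implies the brute-force scanner finds a standalone run."""
        rng = random.Random(11)
        for _ in range(500):
            cell = random_digit_text(rng, rng.randrange(5, 60))
            pos = rng.choice([388, 274, 7, 92])
            assert position_postfilter(cell, pos) == bool(
                digit_run_oracle(cell, pos)
            )


class TestFindRows:
    def test_notation_hit(self, rep):
        store = TableStore([genotype_table(
            [["P1", "c.100A>G", "wt"],
             ["P2", "c.274G>T", "c.35delG"],
             ["P3", "c.200T>C", "wt"]]
        )])
        hits = find_variant_rows(store, rep)
        assert len(hits) == 1
        assert hits[0].row_index == 1
        assert hits[0].confidence == "notation"
        assert hits[0].patient_id == "P2"
        assert hits[0].matched_text == "c.274G>T"

    def test_position_only_hit(self, rep):
        store = TableStore([Table(
            "Table 1", "", ["Patient", "Position"], [["P1", "274"]]
        )])
        hits = find_variant_rows(store, rep)
        assert len(hits) == 1
        assert hits[0].confidence == "position_only"

    def test_decimal_trap_rejected(self):
        rep = augment_variant(parse_hgvs("c.388A>G"))
        store = TableStore([Table(
            "Table 1", "", ["Metric", "Value"],
            [["frequency", "0.93884"]],
        )])
        assert find_variant_rows(store, rep) == []

    def test_batching_equivalence(self, rep):
        """Hits are identical whether tables run in one pass or batches."""
        rng = random.Random(5)
        tables = []
        for i in range(12):
            rows = []
            for j in range(rng.randrange(1, 5)):
                cell = "c.274G>T" if rng.random() < 0.3 else f"c.{rng.randrange(10, 99)}A>G"
                rows.append([f"P{j}", cell, "wt"])
            tables.append(genotype_table(rows, label=f"Table {i + 1}"))
        full = find_variant_rows(load_tables(tables), rep)
        batched = []
        for batch in batch_tables(tables, 5):
            batched.extend(find_variant_rows(load_tables(batch), rep))
        key = lambda h: (h.table_label, h.row_index, h.confidence)
        assert sorted(map(key, full)) == sorted(map(key, batched))


class TestInTransRows:
    def make_store(self):
        t = genotype_table(
            [["P0", "c.5A>G", ""],
             ["P1", "c.274G>T", ""],
             ["P1", "c.35delG", ""],
             ["P2", "c.9C>T", ""],
             ["P1", "c.999G>A", ""]],
            header=("Patient", "Allele", "Status"),
        )
        return TableStore([t])

    def hit(self, store, rep):
        (h,) = [x for x in find_variant_rows(store, rep)
                if x.confidence == "notation"]
        return h

    def test_sibling_row_returned(self, rep):
        store = self.make_store()
        h = self.hit(store, rep)
        rows = extract_in_trans_rows(store, h)
        assert [r.row_index for r in rows] == [2]
        assert rows[0].row_cells[1] == "c.35delG"

    def test_block_above_and_below(self, rep):
        t = genotype_table(
            [["A", "x", ""], ["B", "y", ""], ["B", "c.274G>T", ""],
             ["B", "z", ""], ["C", "w", ""]],
            header=("ID", "Allele", "Status"),
        )
        store = TableStore([t])
        h = self.hit(store, rep)
        assert [r.row_index for r in extract_in_trans_rows(store, h)] == [1, 3]

    def test_singleton_patient(self, rep):
        t = genotype_table([["P1", "c.274G>T", ""]],
                           header=("ID", "Allele", "Status"))
        store = TableStore([t])
        h = self.hit(store, rep)
        assert extract_in_trans_rows(store, h) == []

    def test_distant_same_id_reported_separately(self, rep):
        store = self.make_store()
        h = self.hit(store, rep)
        distant = distant_same_id_rows(store, h)
        assert [r.row_index for r in distant] == [4]
        assert distant[0].confidence == "position_only"

    def test_id_block_property(self, rep):
        """Exactly the contiguous same-ID rows come back, hit excluded."""
        rng = random.Random(3)
        for _ in range(50):
            ids = [rng.choice("AB") for _ in range(rng.randrange(2, 10))]
            target = rng.randrange(len(ids))
            rows = [[pid, "c.274G>T" if i == target else f"c.{10 + i}A>G", ""]
                    for i, pid in enumerate(ids)]
            store = TableStore([genotype_table(
                rows, header=("ID", "Allele", "Status"))])
            h = self.hit(store, rep)
            got = {r.row_index for r in extract_in_trans_rows(store, h)}
            want = set()
            for r in range(target - 1, -1, -1):
                if ids[r] != ids[target]:
                    break
                want.add(r)
            for r in range(target + 1, len(ids)):
                if ids[r] != ids[target]:
                    break
                want.add(r)
            assert got == want


class TestBatching:
    @pytest.mark.parametrize(
        "n,sizes", [(7, [5, 2]), (5, [5]), (12, [5, 5, 2]), (1, [1]), (0, [])]
    )
    def test_batch_sizes(self, n, sizes):
        tables = [genotype_table([["P", "a", "b"]], label=f"T{i}")
                  for i in range(n)]
        batches = batch_tables(tables, 5)
        assert [len(b) for b in batches] == sizes
        flat = [t.table_label for b in batches for t in b]
        assert flat == [t.table_label for t in tables]

    def test_invalid_batch_size(self):
        with pytest.raises(ValueError):
            batch_tables([], 0)
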