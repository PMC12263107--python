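import random

import pytest
from hypothesis import HealthCheck, settings

from pm3kit.bioc import read_bioc
from pm3kit.synth import generate_cds
from pm3kit.variants import augment_variant, parse_hgvs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cds_gac92() -> str:
    """CDS whose codon 92 is GAC, so c.274G>T gives Asp92Tyr / D92Y."""
    return generate_cds(110, {92: "GAC"}, seed=1)


@pytest.fixture(scope="session")
def cds_tgg24() -> str:
    """CDS whose codon 24 is TGG, so c.71G>A gives Trp24Ter / W24*."""
    return generate_cds(40, {24: "TGG"}, seed=1)


@pytest.fixture(scope="session")
def rep_274(cds_gac92):
    return augment_variant(parse_hgvs("c.274G>T"), cds_gac92)


def bioc_doc(passages, tables=(), doc_id="TEST1") -> bytes:
    """Hand-rolled BioC XML for unit fixtures.

    ``passages``: list of (section, text); ``tables``: list of
    (label, caption, header_row, rows) rendered as tab-separated grids.
    """
    parts = ['<?xml version="1.0" encoding="UTF-8"?>', "<collection>",
             "<source>test</source><date>20250101</date><key>k</key>",
             f"<document><id>{doc_id}</id>"]
    offset = 0

    def esc(s: str) -> str:
        return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")

    for section, text in passages:
        parts.append(
            f'<passage><infon key="type">{section}</infon>'
            f"<offset>{offset}</offset><text>{esc(text)}</text></passage>"
        )
        offset += len(text) + 1
    for label, caption, header, rows in tables:
        grid = "\n".join(["\t".join(header)] + ["\t".join(r) for r in rows])
        parts.append(
            '<passage><infon key="type">table</infon>'
            f'<infon key="table_label">{esc(label)}</infon>'
            f'<infon key="caption">{esc(caption)}</infon>'
            f"<offset>{offset}</offset><text>{esc(grid)}</text></passage>"
        )
        offset += len(grid) + 1
    parts.append("</document></collection>")
    return "".join(parts).encode()


@pytest.fixture
def make_bundle():
    def _make(passages, tables=(), doc_id="TEST1"):
        return read_bioc(bioc_doc(passages, tables, doc_id))

    return _make


def digit_run_oracle(text: str, value: int) -> list[int]:
    """Brute-force standalone-digit scanner (independent of the regexes).

    Enumerates maximal digit runs and keeps those equal to ``str(value)``
    that are not the fractional part of a decimal number.
    """
    runs = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            runs.append((i, text[i:j]))
            i = j
        else:
            i += 1
    target = str(value)
    out = []
    for start, run in runs:
        if run != target:
            continue
        if start >= 2 and text[start - 1] == "." and text[start - 2].isdigit():
            continue
        out.append(start)
    return out


def random_digit_text(rng: random.Random, length: int = 300) -> str:
    words = ["frequency", "is", "patient", "carried", "variant", "rs", "c.",
             "exon", "allele", "of", "the", "table", "row", "p."]
    parts = []
    total = 0
    while total < length:
        roll = rng.random()
        if roll < 0.4:
            w = rng.choice(words)
        elif roll < 0.7:
            w = str(rng.randrange(0, 9999))
        else:
            w = f"{rng.random() * 10:.{rng.randrange(1, 6)}f}"
        parts.append(w)
        total += len(w) + 1
    return " ".join(parts)
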