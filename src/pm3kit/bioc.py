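"""Reading BioC full-text XML and chunking prose for retrieval.

A publication arrives as BioC XML (the interchange format served by the
PMC Open Access API): one ``<document>`` holding ordered ``<passage>``
elements. Passages flagged as tables are lifted out of the prose stream
into structured :class:`Table` objects so the table and text channels of
the pipeline never see each other's content. The remaining prose is
concatenated and split into fixed-length, overlapping chunks for the
variant-specific retriever.

Table passages carry their grid as tab-separated lines in the passage
``<text>`` (header row first), with ``table_label`` and ``caption``
infons; a preceding ``table_caption`` passage is also honoured. All
character coordinates are 0-based half-open offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from lxml import etree


class MalformedXMLError(ValueError):
    """Input is not well-formed BioC XML."""


class EmptyDocumentError(ValueError):
    """The BioC document holds no passages at all."""


@dataclass(frozen=True)
class Passage:
    section: str
    text: str


@dataclass
class Table:
    table_label: str
    caption: str
    header: list[str]
    rows: list[list[str]]


@dataclass
class DocumentBundle:
    """One publication, split into ordered prose passages and tables."""

    doc_id: str
    passages: list[Passage]
    tables: list[Table]


@dataclass(frozen=True)
class Chunk:
    text: str
    start: int
    end: int
    source_passage: str

    def __post_init__(self) -> None:
        assert self.end - self.start == len(self.text)


_TABLE_TYPES = {"table"}
_CAPTION_TYPES = {"table_caption"}
_SKIP_TYPES = {"table_foot"}


def _infons(elem) -> dict[str, str]:
    return {i.get("key"): (i.text or "") for i in elem.findall("infon")}


def _parse_table_text(text: str) -> tuple[list[str], list[list[str]]]:
    """Tab-separated grid → (header, rows); short rows padded to width."""
    lines = [ln for ln in text.split("\n") if ln.strip() != ""]
    if not lines:
        return [], []
    header = lines[0].split("\t")
    width = len(header)
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) < width:
            cells = cells + [""] * (width - len(cells))
        rows.append(cells)
    return header, rows


def read_bioc(xml_bytes: bytes) -> DocumentBundle:
    """Parse BioC XML into a :class:`DocumentBundle`.

    Raises :class:`MalformedXMLError` for syntactically broken XML and
    :class:`EmptyDocumentError` when no passages are present.
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise MalformedXMLError(str(exc)) from exc

    doc = root.find(".//document")
    if doc is None:
        raise EmptyDocumentError("no <document> element in BioC input")
    doc_id = (doc.findtext("id") or "").strip()

    passages: list[Passage] = []
    tables: list[Table] = []
    pending_caption: Optional[str] = None
    n_tables = 0

    passage_elems = doc.findall("passage")
    if not passage_elems:
        raise EmptyDocumentError(f"document {doc_id!r} has no passages")

    for p in passage_elems:
        infons = _infons(p)
        ptype = (infons.get("type") or infons.get("section_type") or "").lower()
        text = p.findtext("text") or ""
        if ptype in _CAPTION_TYPES:
            pending_caption = text
            continue
        if ptype in _SKIP_TYPES:
            continue
        if ptype in _TABLE_TYPES:
            n_tables += 1
            header, rows = _parse_table_text(text)
            tables.append(
                Table(
                    table_label=infons.get("table_label") or f"Table {n_tables}",
                    caption=infons.get("caption") or pending_caption or "",
                    header=header,
                    rows=rows,
                )
            )
            pending_caption = None
            continue
        section = infons.get("section_type") or infons.get("type") or "text"
        passages.append(Passage(section=section, text=text))

    if not passages and not tables:
        raise EmptyDocumentError(f"document {doc_id!r} has no passages")
    return DocumentBundle(doc_id=doc_id, passages=passages, tables=tables)


# --- chunking --------------------------------------------------------------

# Preferred break points, strongest first; "" means a hard cut.
SEPARATORS: tuple[str, ...] = ("\n\n", "\n", ". ", " ", "")

PASSAGE_JOINER = "\n\n"


def split_text(
    text: str,
    chunk_size: int = 1500,
    overlap: int = 100,
    source_passage: str = "text",
) -> list[Chunk]:
    """Split prose into overlapping chunks of at most ``chunk_size`` chars.

    Breaks preferentially at paragraph, newline, sentence and word
    boundaries (searched in the later half of the window so chunks stay
    near full length); when no separator is available the cut is hard and
    consecutive chunks share exactly ``overlap`` characters. Every
    character of the input belongs to at least one chunk.
    """
    if not chunk_size > overlap >= 0:
        raise ValueError(f"need chunk_size > overlap >= 0, got {chunk_size}/{overlap}")
    if not text:
        return []
    chunks: list[Chunk] = []
    start = 0
    n = len(text)
    while True:
        end = start + chunk_size
        if end >= n:
            chunks.append(Chunk(text[start:n], start, n, source_passage))
            break
        break_at = end
        lo = start + chunk_size // 2
        for sep in SEPARATORS:
            if sep == "":
                break
            idx = text.rfind(sep, lo, end)
            if idx != -1:
                break_at = idx + len(sep)
                break
        chunks.append(Chunk(text[start:break_at], start, break_at, source_passage))
        start = max(break_at - overlap, start + 1)
    return chunks


def chunk_passages(
    passages: Sequence[Passage], chunk_size: int = 1500, overlap: int = 100
) -> list[Chunk]:
    """Concatenate prose passages and chunk the combined text.

    Each chunk's ``source_passage`` is the section label at its start
    offset; offsets index into the joined prose (sections joined with a
    blank line).
    """
    if not passages:
        return []
    joined_parts: list[str] = []
    bounds: list[tuple[int, str]] = []  # (start offset of section, label)
    offset = 0
    for i, p in enumerate(passages):
        if i:
            joined_parts.append(PASSAGE_JOINER)
            offset += len(PASSAGE_JOINER)
        bounds.append((offset, p.section))
        joined_parts.append(p.text)
        offset += len(p.text)
    joined = "".join(joined_parts)

    def label_at(pos: int) -> str:
        lab = bounds[0][1]
        for b, sec in bounds:
            if b <= pos:
                lab = sec
            else:
                break
        return lab

    raw = split_text(joined, chunk_size=chunk_size, overlap=overlap)
    return [Chunk(c.text, c.start, c.end, label_at(c.start)) for c in raw]
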