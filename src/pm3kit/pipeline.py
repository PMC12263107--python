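"""End-to-end PM3 evidence extraction for one (variant, publication) pair.

The flow: parse and augment the query variant, then run two independent
evidence channels over the publication —

* the **table channel** loads every table into SQLite, finds rows
  carrying the variant (notation match or position match surviving the
  digit-boundary post-filter), and expands hits to same-patient
  neighbour rows for in trans candidates;
* the **text channel** chunks the prose, retrieves variant-bearing
  chunks with the tiered patterns, and asks the completion backend the
  predefined variant-hit and in trans questions over that context.

A variant hit is declared when either channel finds evidence (tables and
prose each contribute true positives that the other misses). Every
answer item carries provenance back to a concrete table row or chunk
span, so a curator can verify it in the source document.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from .backends import Backend, BackendRequest, MockBackend
from .bioc import Chunk, DocumentBundle, chunk_passages
from .evaluation import variant_equivalent
from .retriever import RetrievalResult, RetrieverConfig, retrieve
from .tables import (
    TableHit,
    batch_tables,
    distant_same_id_rows,
    extract_in_trans_rows,
    find_variant_rows,
    load_tables,
)
from .variants import (
    RepresentationSet,
    VariantDescriptor,
    augment_variant,
    parse_hgvs,
)

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    retriever: RetrieverConfig = field(default_factory=RetrieverConfig)
    max_tables_per_batch: int = 5
    enable_tables: bool = True
    enable_text: bool = True


@dataclass
class ProvenanceItem:
    channel: str  # "table" | "text"
    confidence: str  # "notation" | "position_only"
    table_label: Optional[str] = None
    row_index: Optional[int] = None  # 0-based; display as row_index + 1
    row_text: Optional[str] = None
    chunk_start: Optional[int] = None
    chunk_end: Optional[int] = None
    rationale: Optional[str] = None

    def display(self) -> str:
        if self.channel == "table":
            return f"Source: {self.table_label}, row {self.row_index + 1}"
        return f"Source: text chunk {self.chunk_start}-{self.chunk_end}"


@dataclass
class EvidenceAnswer:
    variant_hit: bool
    in_trans: list[str]
    provenance: list[ProvenanceItem]

    def __post_init__(self) -> None:
        if not self.variant_hit and self.in_trans:
            raise ValueError("in_trans candidates require a variant hit")


def _table_provenance(hit: TableHit) -> ProvenanceItem:
    return ProvenanceItem(
        channel="table",
        confidence=hit.confidence,
        table_label=hit.table_label,
        row_index=hit.row_index,
        row_text="\t".join(hit.row_cells),
    )


def _render_rows(hits: Sequence[TableHit]) -> str:
    return "\n".join(
        f"{h.patient_id}\t" + "\t".join(h.row_cells) for h in hits
    )


@dataclass
class _ChannelDetails:
    """Internal per-channel working state shared by the two answers."""

    repset: RepresentationSet
    table_hits: list[TableHit]
    stores: list  # TableStore per batch, aligned with table_hits origin
    hit_store: dict[int, object]  # index in table_hits -> its store
    retrieval: Optional[RetrievalResult]
    text_verdict: str
    text_rationale: str


def _run_channels(
    bundle: DocumentBundle,
    variant: VariantDescriptor,
    cds: Optional[str],
    backend: Backend,
    config: PipelineConfig,
) -> _ChannelDetails:
    repset = augment_variant(variant, cds)

    table_hits: list[TableHit] = []
    stores: list = []
    hit_store: dict[int, object] = {}
    if config.enable_tables and bundle.tables:
        for batch in batch_tables(bundle.tables, config.max_tables_per_batch):
            store = load_tables(batch)
            stores.append(store)
            for h in find_variant_rows(store, repset, backend=backend):
                hit_store[len(table_hits)] = store
                table_hits.append(h)

    retrieval: Optional[RetrievalResult] = None
    verdict = "no"
    rationale = ""
    if config.enable_text and bundle.passages:
        chunks = chunk_passages(
            bundle.passages,
            chunk_size=config.retriever.chunk_size,
            overlap=config.retriever.overlap,
        )
        retrieval = retrieve(chunks, repset, config.retriever)
        if retrieval.chunks:
            context = "\n\n".join(c.text for c in retrieval.chunks)
            answer = backend.complete(
                BackendRequest(
                    task="variant_hit", context=context, variant_forms=repset
                )
            )
            verdict = answer.verdict
            rationale = answer.rationale_span

    return _ChannelDetails(
        repset=repset,
        table_hits=table_hits,
        stores=stores,
        hit_store=hit_store,
        retrieval=retrieval,
        text_verdict=verdict,
        text_rationale=rationale,
    )


def _coerce_variant(variant) -> VariantDescriptor:
    if isinstance(variant, VariantDescriptor):
        return variant
    return parse_hgvs(variant)


def answer_variant_hit(
    bundle: DocumentBundle,
    variant,
    cds: Optional[str] = None,
    backend: Optional[Backend] = None,
    config: Optional[PipelineConfig] = None,
) -> EvidenceAnswer:
    """Is the query variant reported in this publication?

    The verdict is the OR of the two channels: any accepted table row, or
    a yes from the backend over the retrieved chunks. Provenance lists
    every contributing table row and, for the text channel, the chunk
    spans with the backend's quoted rationale.
    """
    backend = backend or MockBackend()
    config = config or PipelineConfig()
    d = _run_channels(bundle, _coerce_variant(variant), cds, backend, config)

    provenance = [_table_provenance(h) for h in d.table_hits]
    if d.text_verdict == "yes" and d.retrieval is not None:
        for chunk, conf in zip(d.retrieval.chunks, d.retrieval.confidences):
            provenance.append(
                ProvenanceItem(
                    channel="text",
                    confidence=conf,
                    chunk_start=chunk.start,
                    chunk_end=chunk.end,
                    rationale=d.text_rationale or None,
                )
            )
    hit = bool(d.table_hits) or d.text_verdict == "yes"
    return EvidenceAnswer(variant_hit=hit, in_trans=[], provenance=provenance)


def answer_in_trans(
    bundle: DocumentBundle,
    variant,
    cds: Optional[str] = None,
    backend: Optional[Backend] = None,
    config: Optional[PipelineConfig] = None,
) -> EvidenceAnswer:
    """Which variants are in trans with the query in the same patient?

    Requires a variant hit first (no hit → empty answer). Table-channel
    candidates come from backend extraction over each hit row plus its
    contiguous same-patient neighbour rows; text-channel candidates from
    backend extraction over the retrieved chunks. Candidates are merged
    and deduplicated up to notation equivalence.
    """
    backend = backend or MockBackend()
    config = config or PipelineConfig()
    v = _coerce_variant(variant)
    d = _run_channels(bundle, v, cds, backend, config)

    hit = bool(d.table_hits) or d.text_verdict == "yes"
    if not hit:
        return EvidenceAnswer(variant_hit=False, in_trans=[], provenance=[])

    candidates: list[str] = []
    provenance: list[ProvenanceItem] = []

    def _add(cand: str, item: ProvenanceItem) -> None:
        if not any(variant_equivalent(cand, seen, cds) for seen in candidates):
            candidates.append(cand)
            provenance.append(item)

    for i, h in enumerate(d.table_hits):
        store = d.hit_store[i]
        neighbours = extract_in_trans_rows(store, h)
        distant = distant_same_id_rows(store, h)
        context_rows = [h, *neighbours]
        answer = backend.complete(
            BackendRequest(
                task="in_trans",
                context=_render_rows(context_rows),
                variant_forms=d.repset,
            )
        )
        for cand in answer.extracted_variants:
            src = next(
                (r for r in context_rows if cand in "\t".join(r.row_cells)), h
            )
            _add(
                cand,
                ProvenanceItem(
                    channel="table",
                    confidence=h.confidence,
                    table_label=src.table_label,
                    row_index=src.row_index,
                    row_text="\t".join(src.row_cells),
                ),
            )
        for r in distant:
            answer = backend.complete(
                BackendRequest(
                    task="in_trans",
                    context=_render_rows([r]),
                    variant_forms=d.repset,
                )
            )
            for cand in answer.extracted_variants:
                _add(cand, _table_provenance(r))

    if d.retrieval is not None and d.retrieval.chunks:
        context = "\n\n".join(c.text for c in d.retrieval.chunks)
        answer = backend.complete(
            BackendRequest(task="in_trans", context=context, variant_forms=d.repset)
        )
        for cand in answer.extracted_variants:
            src = next(
                (
                    (c, conf)
                    for c, conf in zip(d.retrieval.chunks, d.retrieval.confidences)
                    if cand in c.text
                ),
                (d.retrieval.chunks[0], d.retrieval.confidences[0]),
            )
            _add(
                cand,
                ProvenanceItem(
                    channel="text",
                    confidence=src[1],
                    chunk_start=src[0].start,
                    chunk_end=src[0].end,
                    rationale=cand,
                ),
            )

    return EvidenceAnswer(variant_hit=True, in_trans=candidates, provenance=provenance)


# --- report ----------------------------------------------------------------


def run_pair(
    bundle: DocumentBundle,
    variant,
    cds: Optional[str] = None,
    backend: Optional[Backend] = None,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Full report for one (variant, publication) pair as a JSON-able dict."""
    backend = backend or MockBackend()
    config = config or PipelineConfig()
    v = _coerce_variant(variant)
    hit = answer_variant_hit(bundle, v, cds, backend, config)
    trans = answer_in_trans(bundle, v, cds, backend, config)

    summary = ""
    source_items = trans.provenance or hit.provenance
    if source_items:
        lines = []
        for p in source_items:
            detail = (p.row_text or p.rationale or "").replace("\t", " | ")
            lines.append(f"{p.display()} | {detail}")
        ans = backend.complete(
            BackendRequest(task="summarize", context="\n".join(lines))
        )
        summary = ans.rationale_span

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "doc_id": bundle.doc_id,
        "query": {
            "raw": v.raw,
            "canonical": v.canonical,
            "transcript": v.transcript,
            "cds_position": v.cds_position,
            "kind": v.kind.value,
        },
        "variant_hit": {
            "value": hit.variant_hit,
            "provenance": [asdict(p) for p in hit.provenance],
        },
        "in_trans": {
            "variants": trans.in_trans,
            "provenance": [asdict(p) for p in trans.provenance],
        },
        "summary": summary,
    }


def validate_report(report: dict) -> None:
    """Check the report dict against the versioned output shape."""
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("missing or unknown schema_version")
    for key in ("doc_id", "query", "variant_hit", "in_trans", "summary"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    if not isinstance(report["variant_hit"].get("value"), bool):
        raise ValueError("variant_hit.value must be boolean")
    if not isinstance(report["in_trans"].get("variants"), list):
        raise ValueError("in_trans.variants must be a list")
    for section in ("variant_hit", "in_trans"):
        for item in report[section]["provenance"]:
            if item.get("channel") not in ("table", "text"):
                raise ValueError("provenance channel must be table or text")
            if item.get("confidence") not in ("notation", "position_only"):
                raise ValueError("provenance confidence invalid")


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
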