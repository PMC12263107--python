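"""Variant-specific chunk retrieval with tiered pattern relaxation.

The retriever scans prose chunks with the strict full-notation patterns
first. Only when too few chunks match does it relax to digits-only
matching, and then to a ±tolerance window around the variant position —
positions can differ slightly between reference sequences, so e.g. a
query at c.274 may appear as 272–276 in another numbering. At most
``max_chunks`` chunks are returned, in document order; chunks whose only
evidence is a digit-tier match are flagged position-only so downstream
consumers can report them as low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bioc import Chunk
from .variants import (
    PatternMatch,
    RepresentationSet,
    Tier,
    compile_patterns,
)


@dataclass
class RetrieverConfig:
    max_chunks: int = 5
    min_chunks_before_relax: int = 1
    tolerance: int = 2
    chunk_size: int = 1500
    overlap: int = 100

    def __post_init__(self) -> None:
        if self.max_chunks < 1:
            raise ValueError("max_chunks must be >= 1")
        if not self.chunk_size > self.overlap >= 0:
            raise ValueError("need chunk_size > overlap >= 0")


@dataclass
class RetrievalResult:
    chunks: list[Chunk]
    tier_used: Tier
    matches: list[list[PatternMatch]]  # parallel to chunks
    confidences: list[str]  # "notation" | "position_only", parallel to chunks
    tiers_consulted: list[Tier] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.chunks)


def retrieve(
    chunks: list[Chunk],
    representation_set: RepresentationSet,
    config: RetrieverConfig | None = None,
) -> RetrievalResult:
    """Return up to ``max_chunks`` variant-bearing chunks.

    Tiers are consulted strictest-first and relaxation stops as soon as at
    least ``min_chunks_before_relax`` chunks match (matches found at
    stricter tiers are kept when a tier is relaxed). With no match at any
    tier the result is empty with ``tier_used == T2_tolerant``.
    """
    config = config or RetrieverConfig()
    tiers = (Tier.T0_FULL, Tier.T1_DIGITS, Tier.T2_TOLERANT)
    matched: dict[int, tuple[Tier, list[PatternMatch]]] = {}
    consulted: list[Tier] = []
    tier_used = tiers[-1]
    for tier in tiers:
        consulted.append(tier)
        pats = compile_patterns(
            representation_set, tier, tolerance=config.tolerance
        )
        for i, chunk in enumerate(chunks):
            if i in matched:
                continue
            hits = pats.finditer(chunk.text)
            if hits:
                matched[i] = (tier, hits)
        tier_used = tier
        if len(matched) >= config.min_chunks_before_relax:
            break

    keep = sorted(matched)[: config.max_chunks]
    return RetrievalResult(
        chunks=[chunks[i] for i in keep],
        tier_used=tier_used,
        matches=[matched[i][1] for i in keep],
        confidences=[
            "notation" if matched[i][0] is Tier.T0_FULL else "position_only"
            for i in keep
        ],
        tiers_consulted=consulted,
    )
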