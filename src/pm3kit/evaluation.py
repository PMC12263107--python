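"""Benchmark records, shuffled negatives, and scoring.

Variant-hit detection is scored as binary classification: for every
positive (variant, publication) pair an equal number of negatives is
built by reassigning each publication a real query variant from a
*different* record — a seeded derangement — so negatives are genuine
variants that are simply not reported in that document. In trans
detection is scored by recall over the curated truth variants, with
predictions matched to truth through a notation-robust equivalence
relation (transcript prefixes ignored; protein spellings recognised via
augmentation when a CDS is available).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .bioc import DocumentBundle
from .variants import (
    RepresentationSet,
    Tier,
    UnsupportedNotationError,
    augment_variant,
    compile_patterns,
    parse_hgvs,
)


class SchemaError(ValueError):
    """A benchmark record violates the expected JSON shape."""


class ExhaustionError(RuntimeError):
    """No valid negative assignment exists within the retry budget."""


@dataclass
class BenchRecord:
    variant: str
    doc_id: str
    truth_in_trans: list[str] = field(default_factory=list)
    n_probands: int = 0
    label: str = "positive"  # positive | negative


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "f1": self.f1,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


# --- reading ---------------------------------------------------------------

_REQUIRED_FIELDS = ("variant", "doc_id")


def read_bench(json_file) -> list[BenchRecord]:
    """Read benchmark records from a JSON file (a list of objects).

    Each record needs ``variant`` and ``doc_id`` strings; optional
    ``truth_in_trans`` (list of strings), ``n_probands`` (non-negative
    int) and ``label``. The shape is documented in
    ``pm3kit/resources/pm3bench.schema.json``; violations raise
    :class:`SchemaError` naming the offending record.
    """
    if hasattr(json_file, "read"):
        data = json.load(json_file)
    else:
        with open(json_file, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    if not isinstance(data, list):
        raise SchemaError("benchmark file must hold a JSON list of records")
    records: list[BenchRecord] = []
    for i, rec in enumerate(data):
        where = f"record {i}"
        if not isinstance(rec, dict):
            raise SchemaError(f"{where}: not a JSON object")
        for key in _REQUIRED_FIELDS:
            if key not in rec or not isinstance(rec[key], str) or not rec[key]:
                raise SchemaError(f"{where}: missing or invalid {key!r}")
        truth = rec.get("truth_in_trans", [])
        if not isinstance(truth, list) or any(not isinstance(t, str) for t in truth):
            raise SchemaError(f"{where}: truth_in_trans must be a list of strings")
        n_probands = rec.get("n_probands", 0)
        if not isinstance(n_probands, int) or n_probands < 0:
            raise SchemaError(f"{where}: n_probands must be a non-negative integer")
        label = rec.get("label", "positive")
        if label not in ("positive", "negative"):
            raise SchemaError(f"{where}: label must be positive or negative")
        records.append(
            BenchRecord(
                variant=rec["variant"],
                doc_id=rec["doc_id"],
                truth_in_trans=list(truth),
                n_probands=n_probands,
                label=label,
            )
        )
    return records


# --- negatives -------------------------------------------------------------


def _document_text(bundle: DocumentBundle) -> str:
    parts = [p.text for p in bundle.passages]
    for t in bundle.tables:
        parts.append(t.caption)
        parts.append("\t".join(t.header))
        parts.extend("\t".join(row) for row in t.rows)
    return "\n".join(parts)


def _matches_document(variant: str, text: str, tiers: Sequence[Tier]) -> bool:
    try:
        rep = augment_variant(parse_hgvs(variant))
    except UnsupportedNotationError:
        return variant in text
    return any(
        compile_patterns(rep, tier).search(text) is not None for tier in tiers
    )


def make_negatives(
    records: Sequence[BenchRecord],
    corpus: Mapping[str, DocumentBundle],
    seed: int,
    mode: str = "notation",
    max_retries: int = 1000,
) -> list[BenchRecord]:
    """Build one negative per record by derangement of the query variants.

    Each document is assigned the query variant of a *different* record
    (never its own), drawn by seeded shuffling. A pairing is redrawn when
    the assigned variant actually matches the document: in the default
    ``"notation"`` mode a full-notation (T0) match disqualifies; in
    ``"strict"`` mode any tier does, including digit tiers. Raises
    :class:`ExhaustionError` when no valid assignment is found within
    ``max_retries`` shuffles.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to shuffle negatives")
    if mode not in ("notation", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    tiers = (
        (Tier.T0_FULL,)
        if mode == "notation"
        else (Tier.T0_FULL, Tier.T1_DIGITS, Tier.T2_TOLERANT)
    )
    texts = {r.doc_id: _document_text(corpus[r.doc_id]) for r in records}
    rng = random.Random(seed)
    n = len(records)
    idx = list(range(n))
    for _ in range(max_retries):
        rng.shuffle(idx)
        if any(idx[i] == i for i in range(n)):
            continue
        ok = all(
            not _matches_document(
                records[idx[i]].variant, texts[records[i].doc_id], tiers
            )
            for i in range(n)
        )
        if ok:
            return [
                BenchRecord(
                    variant=records[idx[i]].variant,
                    doc_id=records[i].doc_id,
                    truth_in_trans=[],
                    n_probands=0,
                    label="negative",
                )
                for i in range(n)
            ]
    raise ExhaustionError(
        f"no leakage-free derangement of {n} records in {max_retries} shuffles"
    )


# --- equivalence and scoring ----------------------------------------------


def _normalise_opaque(s: str) -> str:
    return "".join(s.split()).lower()


def variant_equivalent(a: str, b: str, cds: Optional[str] = None) -> bool:
    """Notation-robust equality of two variant strings.

    True when both parse to the same coding event (transcript ignored),
    or when either one's augmented representation set — protein spellings
    included when a CDS is supplied — contains the other verbatim.
    Unparseable strings fall back to whitespace/case-normalised equality.
    """
    try:
        da = parse_hgvs(a)
    except UnsupportedNotationError:
        da = None
    try:
        db = parse_hgvs(b)
    except UnsupportedNotationError:
        db = None
    if da is not None and db is not None:
        if (
            da.cds_position == db.cds_position
            and da.kind == db.kind
            and da.ref_base == db.ref_base
            and da.alt_base == db.alt_base
            and da.end_position == db.end_position
        ):
            return True
    for d, other in ((da, b), (db, a)):
        if d is None:
            continue
        try:
            rep = augment_variant(d, cds)
        except ValueError:
            rep = augment_variant(d)
        forms = {_normalise_opaque(f) for f in rep.all_forms()}
        if _normalise_opaque(other) in forms:
            return True
    if da is None and db is None:
        return _normalise_opaque(a) == _normalise_opaque(b)
    return False


def score_variant_hit(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> Metrics:
    """Confusion counts and derived metrics for the variant-hit task.

    The positive class is "the variant is reported in the publication".
    """
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions, {len(labels)} labels"
        )
    tp = fp = tn = fn = 0
    for p, y in zip(predictions, labels):
        if p and y:
            tp += 1
        elif p and not y:
            fp += 1
        elif not p and not y:
            tn += 1
        else:
            fn += 1
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn)


def score_in_trans(
    pred_lists: Sequence[Sequence[str]],
    truth_lists: Sequence[Sequence[str]],
    cds: Optional[str] = None,
    macro: bool = False,
) -> Optional[float]:
    """Recall of curated in trans variants over aligned positive pairs.

    Micro-averaged by default (recovered truth variants / all truth
    variants); ``macro=True`` averages per-pair recalls instead. Pairs
    with empty truth contribute nothing; with no truth variants at all
    the recall is undefined and ``None`` is returned.
    """
    if len(pred_lists) != len(truth_lists):
        raise ValueError(
            f"length mismatch: {len(pred_lists)} prediction lists, "
            f"{len(truth_lists)} truth lists"
        )
    per_pair: list[tuple[int, int]] = []
    for preds, truths in zip(pred_lists, truth_lists):
        if not truths:
            continue
        matched = sum(
            1
            for t in truths
            if any(variant_equivalent(t, p, cds) for p in preds)
        )
        per_pair.append((matched, len(truths)))
    if not per_pair:
        return None
    if macro:
        return sum(m / n for m, n in per_pair) / len(per_pair)
    total_matched = sum(m for m, _ in per_pair)
    total_truth = sum(n for _, n in per_pair)
    return total_matched / total_truth
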