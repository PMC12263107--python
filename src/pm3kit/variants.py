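"""HGVS coding-variant parsing, augmentation, and multi-tier match patterns.

Publications describe the same variant in many spellings: the coding DNA
change (``c.274G>T``), the protein change (``Asp92Tyr``), its one-letter
shorthand (``D92Y``), with or without a transcript accession, with stop
codons written as ``Ter``, ``*`` or ``X``. This module parses a query
variant given in coding notation, derives the protein-level spellings from
an optional coding sequence (CDS), and compiles the resulting
representation set into match patterns at three relaxation tiers:

* ``T0_full`` — full notation, tolerant of whitespace, optional
  parentheses, and X/* interchange;
* ``T1_digits`` — the coding position (and codon index, when known) as a
  standalone digit run;
* ``T2_tolerant`` — as T1 but accepting nearby integers within a
  configurable tolerance, because positions can shift slightly between
  reference sequences.

A digit run is "standalone" when it is not embedded in a longer number and
not the fractional part of a decimal: position 388 must not fire inside
"frequency is 0.93884" or inside "rs3885", but must fire in "c.388A>G".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3


class UnsupportedNotationError(ValueError):
    """Input is not coding-level HGVS this pipeline can handle."""


class ReferenceMismatchError(ValueError):
    """The supplied CDS disagrees with the variant's reference base."""


class CdsRangeError(ValueError):
    """The supplied CDS is too short for the variant position."""


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    DUPLICATION = "duplication"
    DELETION = "deletion"
    INSERTION = "insertion"
    DELINS = "delins"


class Tier(str, Enum):
    """Pattern relaxation tiers, strictest first."""

    T0_FULL = "T0_full"
    T1_DIGITS = "T1_digits"
    T2_TOLERANT = "T2_tolerant"


@dataclass(frozen=True)
class VariantDescriptor:
    """A parsed coding-level variant.

    ``cds_position`` is the 1-based coordinate of the (first) affected
    coding nucleotide. ``end_position`` is set for ranged events
    (``c.10_15del``). ``ref_base``/``alt_base`` are single bases for
    substitutions; for deletions/duplications they hold the stated bases
    when the notation spells them out (``c.35delG``).
    """

    raw: str
    cds_position: int
    kind: VariantKind
    transcript: Optional[str] = None
    end_position: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise UnsupportedNotationError(
                f"coding position must be >= 1, got {self.cds_position}"
            )
        if self.kind is VariantKind.SUBSTITUTION:
            if not (
                self.ref_base
                and self.alt_base
                and len(self.ref_base) == 1
                and len(self.alt_base) == 1
            ):
                raise UnsupportedNotationError(
                    "substitution requires single ref and alt bases"
                )
            if self.ref_base == self.alt_base:
                raise UnsupportedNotationError(
                    f"silent substitution {self.ref_base}>{self.alt_base}"
                )

    @property
    def canonical(self) -> str:
        """Canonical ``c.``-prefixed spelling rebuilt from parsed parts."""
        return "c." + self.bare

    @property
    def bare(self) -> str:
        """Spelling without the ``c.`` prefix (as tables often print it)."""
        if self.kind is VariantKind.SUBSTITUTION:
            return f"{self.cds_position}{self.ref_base}>{self.alt_base}"
        span = str(self.cds_position)
        if self.end_position is not None:
            span += f"_{self.end_position}"
        tail = {
            VariantKind.DUPLICATION: "dup",
            VariantKind.DELETION: "del",
            VariantKind.INSERTION: "ins",
            VariantKind.DELINS: "delins",
        }[self.kind]
        if self.kind is VariantKind.DELETION and self.ref_base:
            tail += self.ref_base
        if self.kind is VariantKind.DUPLICATION and self.ref_base:
            tail += self.ref_base
        if self.kind in (VariantKind.INSERTION, VariantKind.DELINS) and self.alt_base:
            tail += self.alt_base
        return span + tail


@dataclass(frozen=True)
class ProteinChange:
    """Protein-level consequence of a coding substitution."""

    codon_index: int
    ref_aa3: str
    alt_aa3: str
    ref_aa1: str
    alt_aa1: str


@dataclass
class RepresentationSet:
    """All textual spellings of one variant, plus the positions to match."""

    variant: VariantDescriptor
    dna_forms: list[str]
    protein_forms: list[str]
    positions: list[int]
    protein_change: Optional[ProteinChange] = None

    def all_forms(self) -> list[str]:
        return self.dna_forms + self.protein_forms


@dataclass(frozen=True)
class PatternMatch:
    start: int
    end: int
    text: str
    representation: str


@dataclass
class PatternSet:
    """Compiled match patterns for one tier of one representation set."""

    tier: Tier
    patterns: list[tuple[re.Pattern, str]]  # (compiled regex, source repr)
    tolerance: int = 0

    def finditer(self, text: str) -> list[PatternMatch]:
        """All matches in ``text``, sorted by offset, deduplicated by span."""
        seen: dict[tuple[int, int], PatternMatch] = {}
        for regex, rep in self.patterns:
            for m in regex.finditer(text):
                span = (m.start(), m.end())
                if span not in seen:
                    seen[span] = PatternMatch(m.start(), m.end(), m.group(0), rep)
        return [seen[s] for s in sorted(seen)]

    def search(self, text: str) -> Optional[PatternMatch]:
        hits = self.finditer(text)
        return hits[0] if hits else None

    def fullmatch(self, text: str) -> bool:
        return any(regex.fullmatch(text) for regex, _ in self.patterns)


# --- parsing ---------------------------------------------------------------

_TX_RE = re.compile(r"^\s*(?P<tx>[A-Za-z][A-Za-z0-9_]*(?:\.\d+)?)\s*:\s*(?P<rest>.+)$")
_SUB_RE = re.compile(r"^(?P<pos>\d+)\s*(?P<ref>[ACGTacgt])\s*>\s*(?P<alt>[ACGTacgt])$")
_DELINS_RE = re.compile(
    r"^(?P<pos>\d+)(?:_(?P<end>\d+))?delins(?P<ins>[ACGTacgt]+)$"
)
_DEL_RE = re.compile(r"^(?P<pos>\d+)(?:_(?P<end>\d+))?del(?P<seq>[ACGTacgt]*)$")
_DUP_RE = re.compile(r"^(?P<pos>\d+)(?:_(?P<end>\d+))?dup(?P<seq>[ACGTacgt]*)$")
_INS_RE = re.compile(r"^(?P<pos>\d+)_(?P<end>\d+)ins(?P<ins>[ACGTacgt]+)$")


def parse_hgvs(text: str) -> VariantDescriptor:
    """Parse a coding-level HGVS string into a :class:`VariantDescriptor`.

    Accepts an optional transcript prefix with whitespace around the colon
    ("NM_004004.5: c.71G>A"). Genomic ("g."), chromosome-prefixed,
    intronic-offset, UTR and otherwise malformed inputs raise
    :class:`UnsupportedNotationError` — such queries cannot enter the
    pipeline.
    """
    if not text or not text.strip():
        raise UnsupportedNotationError("empty variant string")
    raw = text
    work = text.strip()

    transcript = None
    m = _TX_RE.match(work)
    if m and "c." in m.group("rest"):
        transcript = m.group("tx")
        work = m.group("rest").strip()

    lowered = work.lower()
    if lowered.startswith("chr") or "g." in lowered.split(":")[-1][:4] or \
            re.match(r"^(chr)?[0-9xym]+:", lowered):
        raise UnsupportedNotationError(f"non-coding notation not supported: {text!r}")
    if not work.startswith("c."):
        raise UnsupportedNotationError(f"expected coding ('c.') notation: {text!r}")

    body = work[2:].strip()
    if body.startswith(("-", "*")) or "+" in body or re.search(r"\d-\d", body):
        raise UnsupportedNotationError(
            f"UTR/intronic coordinates not supported: {text!r}"
        )

    m = _SUB_RE.match(body)
    if m:
        return VariantDescriptor(
            raw=raw,
            cds_position=int(m.group("pos")),
            kind=VariantKind.SUBSTITUTION,
            transcript=transcript,
            ref_base=m.group("ref").upper(),
            alt_base=m.group("alt").upper(),
        )
    m = _DELINS_RE.match(body)
    if m:
        return VariantDescriptor(
            raw=raw,
            cds_position=int(m.group("pos")),
            kind=VariantKind.DELINS,
            transcript=transcript,
            end_position=int(m.group("end")) if m.group("end") else None,
            alt_base=m.group("ins").upper(),
        )
    m = _DEL_RE.match(body)
    if m:
        return VariantDescriptor(
            raw=raw,
            cds_position=int(m.group("pos")),
            kind=VariantKind.DELETION,
            transcript=transcript,
            end_position=int(m.group("end")) if m.group("end") else None,
            ref_base=m.group("seq").upper() or None,
        )
    m = _DUP_RE.match(body)
    if m:
        return VariantDescriptor(
            raw=raw,
            cds_position=int(m.group("pos")),
            kind=VariantKind.DUPLICATION,
            transcript=transcript,
            end_position=int(m.group("end")) if m.group("end") else None,
            ref_base=m.group("seq").upper() or None,
        )
    m = _INS_RE.match(body)
    if m:
        return VariantDescriptor(
            raw=raw,
            cds_position=int(m.group("pos")),
            kind=VariantKind.INSERTION,
            transcript=transcript,
            end_position=int(m.group("end")),
            alt_base=m.group("ins").upper(),
        )
    raise UnsupportedNotationError(f"cannot parse variant notation: {text!r}")


# --- coordinates and translation ------------------------------------------


def codon_index(cds_position: int) -> tuple[int, int]:
    """Map a 1-based coding nucleotide position to (codon, offset-in-codon).

    codon = ceil(position / 3); offset in 1..3. Position 274 falls on the
    first base of codon 92.
    """
    if cds_position < 1:
        raise ValueError(f"coding position must be >= 1, got {cds_position}")
    codon = (cds_position + 2) // 3
    offset = cds_position - 3 * (codon - 1)
    return codon, offset


_AA1_FROM_3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}


def translate_protein_change(v: VariantDescriptor, cds: str) -> ProteinChange:
    """Translate a coding substitution into its protein change.

    ``cds`` must start at coding position 1. The reference codon is read
    from the CDS, the in-codon base replaced by the alternate base, and
    both codons translated with the standard genetic code. A stop codon is
    rendered ``Ter`` / ``*``.
    """
    if v.kind is not VariantKind.SUBSTITUTION:
        raise UnsupportedNotationError(
            f"protein translation only defined for substitutions, got {v.kind.value}"
        )
    cds = cds.upper().replace("\n", "").replace(" ", "")
    codon, offset = codon_index(v.cds_position)
    codon_end = 3 * codon
    if len(cds) < codon_end:
        raise CdsRangeError(
            f"CDS length {len(cds)} does not cover codon {codon} "
            f"(needs {codon_end} nt)"
        )
    ref_codon = cds[3 * (codon - 1): codon_end]
    if ref_codon[offset - 1] != v.ref_base:
        raise ReferenceMismatchError(
            f"CDS has {ref_codon[offset - 1]!r} at c.{v.cds_position}, "
            f"variant states {v.ref_base!r}"
        )
    alt_codon = ref_codon[: offset - 1] + v.alt_base + ref_codon[offset:]
    ref_aa1 = str(Seq(ref_codon).translate())
    alt_aa1 = str(Seq(alt_codon).translate())
    return ProteinChange(
        codon_index=codon,
        ref_aa3=seq3(ref_aa1),
        alt_aa3=seq3(alt_aa1),
        ref_aa1=ref_aa1,
        alt_aa1=alt_aa1,
    )


# --- augmentation ----------------------------------------------------------


def augment_variant(
    v: VariantDescriptor, cds: Optional[str] = None
) -> RepresentationSet:
    """Expand a variant into every spelling the literature may use.

    DNA forms always include the canonical ``c.`` form, a
    transcript-prefixed form when a transcript is known, and the bare
    ``<pos><ref>><alt>`` form. When a CDS is supplied (substitutions only)
    the protein forms cover long HGVS (``p.(Asp92Tyr)``), short HGVS,
    bare three-letter, and one-letter shorthand; stop-gain changes are
    spelled with both ``X`` and ``*`` so either typesetting matches.
    """
    dna_forms = [v.canonical]
    if v.transcript:
        dna_forms.append(f"{v.transcript}:{v.canonical}")
    dna_forms.append(v.bare)

    positions = [v.cds_position]
    if v.end_position is not None:
        positions.append(v.end_position)

    protein_forms: list[str] = []
    change: Optional[ProteinChange] = None
    if cds is not None and v.kind is VariantKind.SUBSTITUTION:
        change = translate_protein_change(v, cds)
        c = change.codon_index
        r3, a3 = change.ref_aa3, change.alt_aa3
        r1, a1 = change.ref_aa1, change.alt_aa1
        protein_forms = [
            f"p.({r3}{c}{a3})",
            f"p.{r3}{c}{a3}",
            f"{r3}{c}{a3}",
            f"{r1}{c}{a1}",
        ]
        if a1 == "*" or r1 == "*":

            def _star_x(forms: list[str]) -> list[str]:
                out = []
                for f in forms:
                    out.append(f)
                    if "*" in f:
                        out.append(f.replace("*", "X"))
                    elif "X" in f:
                        out.append(f.replace("X", "*"))
                return out

            star3 = r3.replace("Ter", "*"), a3.replace("Ter", "*")
            protein_forms += [
                f"p.({star3[0]}{c}{star3[1]})",
                f"{star3[0]}{c}{star3[1]}",
            ]
            protein_forms = _star_x(protein_forms)
        # de-duplicate, preserving order
        protein_forms = list(dict.fromkeys(protein_forms))
        positions.append(c)

    return RepresentationSet(
        variant=v,
        dna_forms=list(dict.fromkeys(dna_forms)),
        protein_forms=protein_forms,
        positions=list(dict.fromkeys(positions)),
        protein_change=change,
    )


# --- pattern compilation ---------------------------------------------------

# standalone digit run: not inside a longer number, not the fractional part
# of a decimal ("0.93884" must not yield 388; "c.388A>G" must).
def standalone_digit_regex(value: int) -> re.Pattern:
    return re.compile(rf"(?<!\d)(?<!\d\.)(?:{value})(?!\d)")


def contains_standalone_digits(text: str, value: int) -> bool:
    """True iff ``value`` occurs in ``text`` as a standalone digit run."""
    return standalone_digit_regex(value).search(text) is not None


_TOKEN_RE = re.compile(r"[A-Za-z]+|\d+|\s+|.")


def _compile_full(rep: str, protein: bool) -> re.Pattern:
    """One representation → whitespace/parenthesis/X-*-tolerant regex."""
    parts: list[str] = []
    tokens = _TOKEN_RE.findall(rep)
    for tok in tokens:
        if tok in "()":
            parts.append(r"[()]?")
        elif protein and tok in ("X", "*"):
            parts.append(r"[X*]")
        elif tok.isspace():
            parts.append(r"\s*")
        else:
            parts.append(re.escape(tok))
    body = r"\s*".join(parts)
    if rep[0].isdigit():
        body = r"(?<!\d)(?<!\d\.)" + body
    if rep[-1].isdigit():
        body = body + r"(?!\d)"
    if protein:
        # shorthand like D92Y must not fire inside longer identifiers
        body = r"(?<!\w)" + body + r"(?!\w)"
        return re.compile(body)
    # journals typeset bases inconsistently; match them case-insensitively
    return re.compile(body, re.IGNORECASE)


def compile_patterns(
    r: RepresentationSet, tier: Tier, tolerance: int = 2
) -> PatternSet:
    """Compile a representation set at one relaxation tier.

    T0_full compiles every spelling; T1_digits compiles standalone digit
    runs for each known position; T2_tolerant additionally accepts any
    integer within ``tolerance`` of each position.
    """
    if not r.all_forms():
        raise ValueError("empty representation set")
    if tier is Tier.T0_FULL:
        patterns = [(_compile_full(rep, protein=False), rep) for rep in r.dna_forms]
        patterns += [(_compile_full(rep, protein=True), rep) for rep in r.protein_forms]
        return PatternSet(tier=tier, patterns=patterns, tolerance=0)
    if tier is Tier.T1_DIGITS:
        patterns = [(standalone_digit_regex(p), str(p)) for p in r.positions]
        return PatternSet(tier=tier, patterns=patterns, tolerance=0)
    if tier is Tier.T2_TOLERANT:
        patterns = []
        for p in r.positions:
            for q in range(max(1, p - tolerance), p + tolerance + 1):
                patterns.append((standalone_digit_regex(q), str(p)))
        return PatternSet(tier=tier, patterns=patterns, tolerance=tolerance)
    raise ValueError(f"unknown tier: {tier}")
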