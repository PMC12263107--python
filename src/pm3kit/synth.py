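"""Seeded synthetic publications with known PM3 ground truth.

Real PM3 evidence lives in case reports and genotype tables listing
biallelic genotypes per patient. This module fabricates BioC documents
that emulate exactly that structure — prose passages that may mention the
query variant (optionally "in trans" with a partner variant), genotype
tables in per-patient or per-allele layout keyed by a patient identifier
in the first column, and optional decimal-frequency decoys that embed the
query position inside statistical digits — together with a
:class:`TruthRecord` stating what was planted. Every choice (patient-ID
style, column names, carrier placement, decoy variants) is drawn from a
seeded generator, so the same spec and seed always produce byte-identical
XML.

Vocabulary (ID styles like "P1" / "II-3" / "Family 2, Pt 1"; column pools
like "Allele 1/2", "Nucleotide change") follows conventions of
rare-disease genotype tables and is randomised per seed so the table
engine is never tuned to a single dialect.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from lxml import etree

from .variants import VariantDescriptor, VariantKind, codon_index, parse_hgvs


class ContradictionError(ValueError):
    """Pinned codons conflict with each other or with the ATG start."""


_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NON_STOP_CODONS = sorted(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

_ID_STYLES = ("P{i}", "II-{i}", "Family {f}, Pt {i}", "Pt-{i}")
_ALLELE_HEADER_POOL = (
    ("Allele 1", "Allele 2"),
    ("Nucleotide change 1", "Nucleotide change 2"),
    ("Maternal allele", "Paternal allele"),
)
_PER_ALLELE_HEADER_POOL = ("Nucleotide change", "Allele", "Variant")
_ID_HEADER_POOL = ("Patient", "Case", "Subject ID", "")
_GENE_POOL = ("GJB2", "MYO7A", "USH2A", "ABCA4", "CFTR")

_FILLER_SENTENCES = (
    "Audiological assessment was performed according to standard protocols.",
    "Genomic DNA was extracted from peripheral blood samples.",
    "All participants provided written informed consent.",
    "Sanger sequencing confirmed segregation within each family.",
    "Clinical examinations were repeated at follow-up visits.",
    "The study was approved by the institutional review board.",
    "Exome capture and sequencing followed the manufacturer protocols.",
    "Phenotype severity was graded by two independent clinicians.",
)


def generate_cds(
    n_codons: int,
    constraints: Union[Mapping[int, str], Iterable[tuple[int, str]], None] = None,
    seed: int = 0,
) -> str:
    """Random coding sequence honouring pinned codons.

    Starts with ATG and contains no stop codon outside pinned sites, so a
    substitution anywhere in an unpinned codon has a well-defined protein
    consequence. Conflicting pins (same codon, different triplet, or a
    non-ATG pin at codon 1) raise :class:`ContradictionError`.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    pins: dict[int, str] = {}
    items = (
        constraints.items() if isinstance(constraints, Mapping)
        else (constraints or ())
    )
    for idx, codon in items:
        codon = codon.upper()
        if len(codon) != 3 or any(b not in _BASES for b in codon):
            raise ValueError(f"pin {idx}: {codon!r} is not a DNA codon")
        if not 1 <= idx <= n_codons:
            raise ValueError(f"pin {idx} outside 1..{n_codons}")
        if idx in pins and pins[idx] != codon:
            raise ContradictionError(
                f"codon {idx} pinned to both {pins[idx]} and {codon}"
            )
        pins[idx] = codon
    if pins.get(1, "ATG") != "ATG":
        raise ContradictionError(
            f"codon 1 must be the ATG start, pinned to {pins[1]}"
        )
    rng = random.Random(seed)
    out = []
    for i in range(1, n_codons + 1):
        if i in pins:
            out.append(pins[i])
        elif i == 1:
            out.append("ATG")
        else:
            out.append(rng.choice(_NON_STOP_CODONS))
    return "".join(out)


def cds_for_variant(
    v: VariantDescriptor, n_codons: Optional[int] = None, seed: int = 0
) -> str:
    """A CDS consistent with a substitution's reference base.

    The codon holding the variant position is pinned to a (seeded) non-stop
    codon whose in-codon base equals the variant's reference base.
    """
    if v.kind is not VariantKind.SUBSTITUTION:
        raise ValueError("CDS pinning only defined for substitutions")
    codon, offset = codon_index(v.cds_position)
    if n_codons is None:
        n_codons = codon + 10
    rng = random.Random(seed)
    candidates = [c for c in _NON_STOP_CODONS if c[offset - 1] == v.ref_base]
    if codon == 1:
        if "ATG"[offset - 1] != v.ref_base:
            raise ContradictionError("variant in start codon contradicts ATG")
        pin = "ATG"
    else:
        pin = rng.choice(candidates)
    return generate_cds(n_codons, {codon: pin}, seed=seed)


# --- fixture specification -------------------------------------------------


@dataclass
class FixtureSpec:
    query_variant: str
    in_trans_variant: Optional[str] = None
    n_patients: int = 3
    mention_channels: frozenset = frozenset({"text", "table"})
    trap_decimals: bool = False
    table_layout: str = "one_row_per_patient"  # or "one_row_per_allele"
    seed: int = 0

    def __post_init__(self) -> None:
        self.mention_channels = frozenset(self.mention_channels)
        if not self.mention_channels <= {"text", "table"}:
            raise ValueError(f"unknown channels: {self.mention_channels}")
        if self.table_layout not in ("one_row_per_patient", "one_row_per_allele"):
            raise ValueError(f"unknown table layout: {self.table_layout!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class TruthRecord:
    variant_hit: bool
    in_trans: list[str] = field(default_factory=list)
    patient_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "variant_hit": self.variant_hit,
            "in_trans": list(self.in_trans),
            "patient_ids": list(self.patient_ids),
        }


def _decoy_variant(rng: random.Random, forbidden_positions: set[int]) -> str:
    """A substitution whose position is far from every forbidden one."""
    while True:
        pos = rng.randrange(20, 5000)
        if all(abs(pos - f) > 10 for f in forbidden_positions):
            break
    ref = rng.choice(_BASES)
    alt = rng.choice([b for b in _BASES if b != ref])
    return f"c.{pos}{ref}>{alt}"


def _patient_ids(rng: random.Random, n: int) -> list[str]:
    style = rng.choice(_ID_STYLES)
    return [style.format(i=i + 1, f=(i // 2) + 1) for i in range(n)]


def _query_spelling(rng: random.Random, v: VariantDescriptor) -> str:
    if v.transcript and rng.random() < 0.5:
        return f"{v.transcript}:{v.canonical}"
    return v.canonical


def _trap_cell(pos: int) -> str:
    # embeds the query position inside a decimal, e.g. 388 -> "0.93884"
    return f"0.9{pos}4"


def generate_publication(spec: FixtureSpec) -> tuple[bytes, TruthRecord]:
    """Emit (BioC XML bytes, truth) for one synthetic publication."""
    rng = random.Random(spec.seed)
    query = parse_hgvs(spec.query_variant)
    in_trans = (
        parse_hgvs(spec.in_trans_variant) if spec.in_trans_variant else None
    )
    hit_intended = bool(spec.mention_channels)
    gene = rng.choice(_GENE_POOL)
    ids = _patient_ids(rng, spec.n_patients)
    carrier = rng.randrange(spec.n_patients)
    forbidden = {query.cds_position}
    if query.end_position:
        forbidden.add(query.end_position)
    forbidden.add(codon_index(query.cds_position)[0])
    if in_trans is not None:
        forbidden.add(in_trans.cds_position)

    # --- prose passages ---
    def filler(n: int) -> str:
        return " ".join(rng.choice(_FILLER_SENTENCES) for _ in range(n))

    title = f"Biallelic {gene} variants in {spec.n_patients} unrelated patients"
    intro = filler(5)
    results_bits = [filler(2)]
    if "text" in spec.mention_channels:
        qs = _query_spelling(rng, query)
        if in_trans is not None:
            results_bits.append(
                f"Patient {ids[carrier]} carried {qs} in trans with "
                f"{in_trans.canonical}."
            )
        else:
            results_bits.append(
                f"Patient {ids[carrier]} carried {qs} in a homozygous state."
            )
    if spec.trap_decimals:
        results_bits.append(
            f"The minor allele frequency was {_trap_cell(query.cds_position)} "
            "in population controls."
        )
    results_bits.append(filler(2))
    results = " ".join(results_bits)

    passages = [("title", title), ("intro", intro), ("results", results)]

    # --- genotype table ---
    tables: list[tuple[str, str, list[str], list[list[str]]]] = []
    if "table" in spec.mention_channels:
        id_header = rng.choice(_ID_HEADER_POOL)
        q_cell = _query_spelling(rng, query)
        if spec.table_layout == "one_row_per_patient":
            a1, a2 = rng.choice(_ALLELE_HEADER_POOL)
            header = [id_header, a1, a2]
            rows = []
            for i, pid in enumerate(ids):
                if i == carrier:
                    other = in_trans.canonical if in_trans else q_cell
                    rows.append([pid, q_cell, other])
                else:
                    rows.append(
                        [pid, _decoy_variant(rng, forbidden),
                         _decoy_variant(rng, forbidden)]
                    )
        else:
            allele_col = rng.choice(_PER_ALLELE_HEADER_POOL)
            header = [id_header, allele_col, "Zygosity"]
            repeat_ids = rng.random() < 0.5  # else merged-cell style (blank)
            rows = []
            for i, pid in enumerate(ids):
                first = q_cell if i == carrier else _decoy_variant(rng, forbidden)
                rows.append([pid, first, "het"])
                second_id = pid if repeat_ids else ""
                if i == carrier:
                    second = in_trans.canonical if in_trans else q_cell
                else:
                    second = _decoy_variant(rng, forbidden)
                rows.append([second_id, second, "het"])
        tables.append(
            ("Table 1", f"Genotypes of the {spec.n_patients} patients",
             header, rows)
        )
    if spec.trap_decimals:
        tables.append(
            (
                f"Table {len(tables) + 1}",
                "Observed allele frequencies",
                ["Position", "Frequency"],
                [
                    ["intronic", _trap_cell(query.cds_position)],
                    ["exonic", f"{rng.random():.4f}"],
                ],
            )
        )

    xml = _to_bioc(f"SYN{spec.seed}", passages, tables)
    truth = TruthRecord(
        variant_hit=hit_intended,
        in_trans=(
            [in_trans.canonical] if hit_intended and in_trans is not None else []
        ),
        patient_ids=[ids[carrier]] if hit_intended else [],
    )
    return xml, truth


def _to_bioc(
    doc_id: str,
    passages: list[tuple[str, str]],
    tables: list[tuple[str, str, list[str], list[list[str]]]],
) -> bytes:
    collection = etree.Element("collection")
    etree.SubElement(collection, "source").text = "pm3kit-synth"
    etree.SubElement(collection, "date").text = "20250101"
    etree.SubElement(collection, "key").text = "pm3kit.key"
    doc = etree.SubElement(collection, "document")
    etree.SubElement(doc, "id").text = doc_id
    offset = 0

    def add_passage(infons: dict[str, str], text: str) -> None:
        nonlocal offset
        p = etree.SubElement(doc, "passage")
        for key, value in infons.items():
            inf = etree.SubElement(p, "infon", key=key)
            inf.text = value
        etree.SubElement(p, "offset").text = str(offset)
        etree.SubElement(p, "text").text = text
        offset += len(text) + 1

    for section, text in passages:
        add_passage({"type": section, "section_type": section}, text)
    for label, caption, header, rows in tables:
        grid = "\n".join(
            ["\t".join(header)] + ["\t".join(r) for r in rows]
        )
        add_passage(
            {"type": "table", "table_label": label, "caption": caption}, grid
        )
    return etree.tostring(
        collection, xml_declaration=True, encoding="UTF-8", pretty_print=False
    )


def write_fixture(
    spec: FixtureSpec, out_dir, include_cds: bool = False
) -> dict[str, str]:
    """Write doc.xml + truth.json (and optionally cds.fa); returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    xml, truth = generate_publication(spec)
    paths = {
        "bioc": os.path.join(out_dir, "doc.xml"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    with open(paths["bioc"], "wb") as fh:
        fh.write(xml)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if include_cds:
        query = parse_hgvs(spec.query_variant)
        cds = cds_for_variant(query, seed=spec.seed)
        paths["cds"] = os.path.join(out_dir, "cds.fa")
        with open(paths["cds"], "w", encoding="utf-8") as fh:
            fh.write(f">synthetic_cds_{spec.seed}\n")
            for i in range(0, len(cds), 60):
                fh.write(cds[i: i + 60] + "\n")
    return paths
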