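"""Parsing, protein translation, augmentation, and tiered patterns."""

import random
import re

import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from pm3kit.synth import generate_cds
from pm3kit.variants import (
    CdsRangeError,
    ReferenceMismatchError,
    Tier,
    UnsupportedNotationError,
    VariantKind,
    augment_variant,
    codon_index,
    compile_patterns,
    contains_standalone_digits,
    parse_hgvs,
    translate_protein_change,
)

from conftest import digit_run_oracle, random_digit_text


class TestParse:
    @pytest.mark.parametrize(
        "text,tx,pos,ref,alt,kind",
        [
            ("NM_004004.5: c.71G>A", "NM_004004.5", 71, "G", "A",
             VariantKind.SUBSTITUTION),
            ("NM_000059.4: c.7796A>G", "NM_000059.4", 7796, "A", "G",
             VariantKind.SUBSTITUTION),
            ("c.1813dup", None, 1813, None, None, VariantKind.DUPLICATION),
            ("c.35delG", None, 35, "G", None, VariantKind.DELETION),
            ("c.10_15del", None, 10, None, None, VariantKind.DELETION),
            ("c.10_11insA", None, 10, None, "A", VariantKind.INSERTION),
            ("c.10_12delinsTT", None, 10, None, "TT", VariantKind.DELINS),
        ],
    )
    def test_accepted_notations(self, text, tx, pos, ref, alt, kind):
        v = parse_hgvs(text)
        assert (v.transcript, v.cds_position, v.ref_base, v.alt_base, v.kind) == (
            tx, pos, ref, alt, kind,
        )

    @pytest.mark.parametrize(
        "text",
        [
            "chr13:g.32398489A>G",
            "g.123A>G",
            "NC_000013.11:g.32398489A>G",
            "c.123+4G>A",
            "c.-12A>G",
            "c.*33A>G",
            "p.Asp92Tyr",
            "",
            "   ",
            "c.71G>G",  # silent: ref == alt
            "nonsense",
        ],
    )
    def test_rejected_notations(self, text):
        with pytest.raises(UnsupportedNotationError):
            parse_hgvs(text)

    def test_parse_is_idempotent(self):
        for text in ("NM_004004.5: c.71G>A", "c.1813dup", "c.35delG"):
            v = parse_hgvs(text)
            assert parse_hgvs(v.raw) == v
            # and the canonical spelling parses to the same coding event
            w = parse_hgvs(v.canonical)
            assert (w.cds_position, w.kind, w.ref_base, w.alt_base) == (
                v.cds_position, v.kind, v.ref_base, v.alt_base,
            )


class TestCodonIndex:
    @pytest.mark.parametrize(
        "pos,codon,offset", [(274, 92, 1), (71, 24, 2), (3, 1, 3), (1, 1, 1)]
    )
    def test_mapping(self, pos, codon, offset):
        assert codon_index(pos) == (codon, offset)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            codon_index(0)

    @given(st.integers(min_value=1, max_value=100000))
    def test_inverse(self, pos):
        codon, offset = codon_index(pos)
        assert 1 <= offset <= 3
        assert 3 * (codon - 1) + offset == pos


class TestTranslate:
    def test_asp92tyr(self, cds_gac92):
        change = translate_protein_change(parse_hgvs("c.274G>T"), cds_gac92)
        assert (change.codon_index, change.ref_aa3, change.alt_aa3) == (
            92, "Asp", "Tyr",
        )
        assert (change.ref_aa1, change.alt_aa1) == ("D", "Y")

    def test_stop_gain(self, cds_tgg24):
        change = translate_protein_change(parse_hgvs("c.71G>A"), cds_tgg24)
        assert (change.codon_index, change.ref_aa3, change.alt_aa3) == (
            24, "Trp", "Ter",
        )
        assert change.alt_aa1 == "*"

    def test_reference_mismatch(self, cds_gac92):
        with pytest.raises(ReferenceMismatchError):
            translate_protein_change(parse_hgvs("c.274A>T"), cds_gac92)

    def test_cds_too_short(self, cds_gac92):
        with pytest.raises(CdsRangeError):
            translate_protein_change(parse_hgvs("c.9999G>T"), cds_gac92)

    def test_agrees_with_full_cds_translation(self):
        """Oracle: codon-wise diff of whole-CDS translation before/after."""
        rng = random.Random(42)
        for trial in range(100):
            n_codons = rng.randrange(5, 60)
            cds = generate_cds(n_codons, seed=trial)
            pos = rng.randrange(4, 3 * n_codons + 1)  # spare the ATG
            ref = cds[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v = parse_hgvs(f"c.{pos}{ref}>{alt}")
            change = translate_protein_change(v, cds)
            mutated = cds[: pos - 1] + alt + cds[pos:]
            before = str(Seq(cds).translate())
            after = str(Seq(mutated).translate())
            diffs = [i for i, (a, b) in enumerate(zip(before, after)) if a != b]
            if before[change.codon_index - 1] == change.alt_aa1:
                assert diffs == []  # synonymous
            else:
                assert diffs == [change.codon_index - 1]
                assert before[diffs[0]] == change.ref_aa1
                assert after[diffs[0]] == change.alt_aa1


class TestAugment:
    def test_dna_and_protein_forms(self, rep_274):
        assert {"c.274G>T", "Asp92Tyr", "D92Y"} <= set(rep_274.all_forms())
        assert "c.274G>T" in rep_274.dna_forms
        assert rep_274.positions == [274, 92]

    def test_stop_has_both_x_and_star(self, cds_tgg24):
        rep = augment_variant(parse_hgvs("c.71G>A"), cds_tgg24)
        assert "W24X" in rep.protein_forms
        assert "W24*" in rep.protein_forms

    def test_x_star_pairing_invariant(self, cds_tgg24):
        rep = augment_variant(parse_hgvs("c.71G>A"), cds_tgg24)
        forms = set(rep.protein_forms)
        for f in forms:
            if "X" in f.replace("Ter", ""):
                assert f.replace("X", "*") in forms
            if "*" in f:
                assert f.replace("*", "X") in forms

    def test_transcript_prefixed_form(self):
        rep = augment_variant(parse_hgvs("NM_004004.5: c.71G>A"))
        assert "NM_004004.5:c.71G>A" in rep.dna_forms
        assert "71G>A" in rep.dna_forms

    def test_no_cds_means_no_protein_forms(self):
        rep = augment_variant(parse_hgvs("c.1813dup"))
        assert rep.protein_forms == []
        assert rep.dna_forms[0] == "c.1813dup"
        assert rep.positions == [1813]


class TestPatterns:
    def test_t0_tolerates_whitespace_and_parens(self, rep_274):
        t0 = compile_patterns(rep_274, Tier.T0_FULL)
        assert t0.search("we found c. 274 G>T in the proband")
        assert t0.search("the substitution p.Asp92Tyr (D92Y)")
        assert t0.search("p.(Asp92Tyr)") and t0.search("p.Asp92Tyr")

    def test_t0_interchanges_x_and_star(self, cds_tgg24):
        rep = augment_variant(parse_hgvs("c.71G>A"), cds_tgg24)
        t0 = compile_patterns(rep, Tier.T0_FULL)
        assert t0.search("the nonsense change W24X")
        assert t0.search("the nonsense change W24*")

    def test_t1_standalone_digits(self, rep_274):
        t1 = compile_patterns(rep_274, Tier.T1_DIGITS)
        assert t1.search("position 274 was affected")
        assert t1.search("c.274G>T")  # 274 after a non-digit dot is standalone
        assert not t1.search("rs2741 was common")
        assert not t1.search("frequency is 0.2744")

    def test_t1_rejects_decimal_fraction(self):
        rep = augment_variant(parse_hgvs("c.388A>G"))
        t1 = compile_patterns(rep, Tier.T1_DIGITS)
        assert not t1.search("frequency is 0.93884")
        assert t1.search("c.388A>G")

    def test_t2_window(self, rep_274):
        t2 = compile_patterns(rep_274, Tier.T2_TOLERANT, tolerance=2)
        assert t2.search("position 272")
        assert t2.search("position 276")
        assert not t2.search("position 271")
        assert not t2.search("position 277")

    def test_self_match_closure(self, rep_274, cds_tgg24):
        """Every augmented spelling is matched by its own T0 patterns."""
        reps = [
            rep_274,
            augment_variant(parse_hgvs("c.71G>A"), cds_tgg24),
            augment_variant(parse_hgvs("NM_004004.5: c.71G>A")),
            augment_variant(parse_hgvs("c.1813dup")),
            augment_variant(parse_hgvs("c.35delG")),
        ]
        for rep in reps:
            t0 = compile_patterns(rep, Tier.T0_FULL)
            for form in rep.all_forms():
                assert t0.search(form), form

    @given(st.integers(min_value=0, max_value=10**6))
    def test_tier_monotonicity(self, seed):
        """Relaxation never loses match offsets: T0 ⊆ +T1 ⊆ +T2."""
        rng = random.Random(seed)
        text = random_digit_text(rng) + " c.274G>T " + random_digit_text(rng, 100)
        rep = augment_variant(parse_hgvs("c.274G>T"))
        offs = []
        acc = set()
        for tier in (Tier.T0_FULL, Tier.T1_DIGITS, Tier.T2_TOLERANT):
            acc |= {m.start for m in compile_patterns(rep, tier).finditer(text)}
            offs.append(set(acc))
        assert offs[0] <= offs[1] <= offs[2]

    def test_t1_agrees_with_brute_force_scanner(self):
        """Oracle equivalence on randomized digit-heavy texts."""
        rng = random.Random(7)
        rep = augment_variant(parse_hgvs("c.388A>G"))
        t1 = compile_patterns(rep, Tier.T1_DIGITS)
        for _ in range(300):
            text = random_digit_text(rng, rng.randrange(50, 400))
            got = sorted(m.start for m in t1.finditer(text))
            want = sorted(digit_run_oracle(text, 388))
            assert got == want, text

    def test_contains_standalone_digits(self):
        assert contains_standalone_digits("c.388A>G", 388)
        assert not contains_standalone_digits("0.93884", 388)
        assert not contains_standalone_digits("3885", 388)
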