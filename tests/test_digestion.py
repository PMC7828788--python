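"""Cleavage engine tests, including an independent brute-force oracle that
re-states each protease rule as direct conditionals on the residue window."""

import re

import pytest

from pepscreen import (
    ValidationError,
    cut_positions,
    digest,
    find_cleavage_sites,
    is_fixed_point,
)
from pepscreen.io import ProteinRecord

from conftest import random_sequences

DEFAULT_SET = ("pepsin_ph2", "trypsin", "chymotrypsin_low")


# --------------------------------------------------------------------------
# independent oracle: plain conditionals, no clause engine

def _oracle_trypsin(seq, i):
    # bond i between residues i and i+1 (1-based); indices below 0-based
    p2 = seq[i - 2] if i >= 2 else None
    p1, q1 = seq[i - 1], seq[i]
    cuts = (p1 in "KR" and q1 != "P") or (p2, p1, q1) in {("W", "K", "P"), ("M", "R", "P")}
    blocked = (
        (p2 in ("C", "D") and p1 == "K" and q1 == "D")
        or (p2 == "C" and p1 == "K" and q1 in ("H", "Y"))
        or (p2 == "C" and p1 == "R" and q1 == "K")
        or (p2 == "R" and p1 == "R" and q1 in ("H", "R"))
    )
    return cuts and not blocked


def _oracle_chymotrypsin(seq, i, low):
    p1, q1 = seq[i - 1], seq[i]
    if p1 in ("FY" + ("L" if low else "")) and q1 != "P":
        return True
    if p1 == "W" and q1 not in "MP":
        return True
    if low and p1 == "M" and q1 not in "PY":
        return True
    if low and p1 == "H" and q1 not in "DMPW":
        return True
    return False


def _oracle_pepsin(seq, i, hydrophobic):
    p3 = seq[i - 3] if i >= 3 else None
    p2 = seq[i - 2] if i >= 2 else None
    p1, q1 = seq[i - 1], seq[i]
    q2 = seq[i + 1] if i + 1 < len(seq) else None
    if p3 is None or p2 is None:
        return False
    if p3 in "HKR" or p2 == "P":
        return False
    if q2 is None or q2 == "P":
        return False
    clause_a = p1 != "R" and q1 in hydrophobic
    clause_b = p1 in hydrophobic
    return clause_a or clause_b


def oracle_sites(seq, enzyme):
    checks = {
        "trypsin": _oracle_trypsin,
        "chymotrypsin_high": lambda s, i: _oracle_chymotrypsin(s, i, low=False),
        "chymotrypsin_low": lambda s, i: _oracle_chymotrypsin(s, i, low=True),
        "pepsin_ph1.3": lambda s, i: _oracle_pepsin(s, i, "FL"),
        "pepsin_ph2": lambda s, i: _oracle_pepsin(s, i, "FLWY"),
    }
    check = checks[enzyme]
    return {i for i in range(1, len(seq)) if check(seq, i)}


ALL_ENZYMES = ("trypsin", "chymotrypsin_high", "chymotrypsin_low", "pepsin_ph1.3", "pepsin_ph2")


class TestFindCleavageSites:
    @pytest.mark.parametrize(
        "sequence,enzyme,expected",
        [
            ("AKPA", "trypsin", set()),          # proline blocks
            ("AKAA", "trypsin", {2}),
            ("AWKPA", "trypsin", {3}),           # WKP overrides the proline block
            ("ACKDA", "trypsin", set()),         # CKD blocking exception
            ("ARRHA", "trypsin", {2}),           # RRH blocks bond 3, not bond 2
            ("AFAA", "chymotrypsin_high", {2}),
            ("AWMA", "chymotrypsin_high", set()),  # W not cleaved before M
            ("ALAA", "chymotrypsin_low", {2}),
            ("ALAA", "chymotrypsin_high", set()),
            ("AAALAAA", "pepsin_ph2", {3, 4}),   # L at P1' (bond 3) and at P1 (bond 4)
            ("AAAYAAA", "pepsin_ph1.3", set()),  # Y is pH>2 only
            ("AAAYAAA", "pepsin_ph2", {3, 4}),
        ],
    )
    def test_known_sites(self, sequence, enzyme, expected):
        assert find_cleavage_sites(sequence, enzyme) == expected

    def test_survivor_peptide_has_no_sites_under_default_set(self):
        assert cut_positions("CCTKPESER", DEFAULT_SET) == set()

    def test_unknown_enzyme_lists_available(self):
        with pytest.raises(ValidationError, match="trypsin"):
            find_cleavage_sites("AAAA", "papain")

    def test_engine_equals_bruteforce_oracle(self, rng):
        for seq in random_sequences(rng, 1000, max_length=50):
            for enzyme in ALL_ENZYMES:
                assert find_cleavage_sites(seq, enzyme) == oracle_sites(seq, enzyme), (
                    seq, enzyme)

    def test_engine_matches_pyteomics_on_interior_bonds(self, rng):
        """Cross-check against the PeptideCutter transcription shipped with
        pyteomics, away from the termini where regex windows are truncated."""
        parser = pytest.importorskip("pyteomics.parser")
        name_map = {
            "trypsin": "trypsin",
            "chymotrypsin_high": "chymotrypsin high specificity",
            "chymotrypsin_low": "chymotrypsin low specificity",
            "pepsin_ph1.3": "pepsin ph1.3",
            "pepsin_ph2": "pepsin ph2.0",
        }

        def regex_sites(seq, pattern):
            return {m.start() + 1 for m in re.finditer(pattern, seq)}

        for seq in random_sequences(rng, 300, max_length=40, min_length=10):
            interior = set(range(4, len(seq) - 2))
            for ours, theirs in name_map.items():
                expected = regex_sites(seq, parser.expasy_rules[theirs])
                if ours == "trypsin":
                    expected -= regex_sites(seq, parser.expasy_rules["trypsin_exception"])
                assert find_cleavage_sites(seq, ours) & interior == expected & interior


class TestDigest:
    def test_no_sites_single_fragment(self):
        protein = ProteinRecord(id="p", sequence="AAAA")
        result = digest(protein, DEFAULT_SET, min_length=1)
        assert [(f.start, f.end, f.sequence) for f in result.fragments] == [(1, 4, "AAAA")]
        assert result.survivors == result.fragments

    def test_fragments_between_cuts(self):
        protein = ProteinRecord(id="p", sequence="AKRA")
        result = digest(protein, ("trypsin",), min_length=1)
        assert [(f.sequence, f.start, f.end) for f in result.fragments] == [
            ("AK", 1, 2), ("R", 3, 3), ("A", 4, 4)]

    def test_min_length_boundary_inclusive(self):
        protein = ProteinRecord(id="p", sequence="AAAAAAAAAKAAAAAAAAA")  # 9 + K + 9
        result = digest(protein, ("trypsin",), min_length=9)
        assert {f.sequence for f in result.survivors} == {"AAAAAAAAAK", "AAAAAAAAA"}

    def test_bos_d4_survivors(self, paper):
        result = digest(paper.proteins["P00711"], DEFAULT_SET, min_length=9)
        assert [(s.sequence, s.start, s.end) for s in result.survivors] == [
            ("DTQAIVQNNDSTE", 56, 68), ("SSNICNISCDK", 88, 98)]

    def test_tiling_and_count_invariants(self, rng):
        for seq in random_sequences(rng, 200, max_length=60, min_length=1):
            protein = ProteinRecord(id="p", sequence=seq)
            result = digest(protein, DEFAULT_SET, min_length=1)
            assert "".join(f.sequence for f in result.fragments) == seq
            assert len(result.fragments) == len(result.cut_positions) + 1
            for frag in result.fragments:
                assert frag.sequence == seq[frag.start - 1 : frag.end]

    def test_union_monotonicity(self, rng):
        for seq in random_sequences(rng, 200, max_length=60, min_length=2):
            base = set()
            for k in range(1, len(ALL_ENZYMES) + 1):
                cuts = cut_positions(seq, ALL_ENZYMES[:k])
                assert base <= cuts
                base = cuts

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            is_fixed_point("")


class TestIsFixedPoint:
    def test_single_residue_is_fixed_point(self):
        assert is_fixed_point("A")

    def test_internal_tryptic_site_detected(self):
        assert not is_fixed_point("AKA", ("trypsin",))

    def test_printed_survivors_are_fixed_points(self, paper):
        assert all(is_fixed_point(p.sequence, DEFAULT_SET) for p in paper.is_peptides)
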