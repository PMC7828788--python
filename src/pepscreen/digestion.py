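"""Rule-based protease cleavage-site prediction and multi-enzyme digestion.

The engine evaluates positional specificity rules (Keil P4..P4' windows,
transcribed from the ExPASy PeptideCutter documentation) at every peptide
bond.  A bond is cut when at least one positive clause of an enzyme's rule
matches and none of its exception clauses do.  Multi-enzyme digestion takes
the union of single-enzyme cut sets on the intact precursor (simultaneous
digestion, not sequential rounds), then keeps the maximal uncut runs.

The default enzyme set — pepsin (pH > 2 variant), trypsin and chymotrypsin
(low-specificity variant) — emulates gastrointestinal digestion of a food
protein.  Applied to the seven bovine milk allergen precursors it leaves
exactly 24 fragments of nine or more residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .io import PeptideFragment, ProteinRecord, Source, ValidationError

# Slot offsets relative to the scissile bond: bond i lies between residue i
# (P1, 1-based) and residue i+1 (P1').
_SLOT_OFFSETS = {
    "P4": -3, "P3": -2, "P2": -1, "P1": 0,
    "P1'": 1, "P2'": 2, "P3'": 3, "P4'": 4,
}


@dataclass(frozen=True)
class SlotConstraint:
    """Constraint on one window slot: an allowed-set or a forbidden-set."""

    kind: str  # "allowed" | "forbidden"
    residues: frozenset[str]


Clause = Mapping[str, SlotConstraint]


@dataclass(frozen=True)
class CleavageRule:
    """Positional specificity of one protease.

    A bond is cut iff at least one clause in ``clauses`` is satisfied and no
    clause in ``exceptions`` is satisfied.  Exception clauses carry the Keil
    blocking patterns (e.g. trypsin's CKD/DKD/CKH/CKY/CRK/RRH/RRR) that a
    pure disjunction of positive clauses cannot express.
    """

    enzyme: str
    clauses: tuple[Clause, ...]
    exceptions: tuple[Clause, ...] = ()

    def __post_init__(self) -> None:
        for clause in self.clauses:
            if "P1" not in clause and "P1'" not in clause:
                raise ValidationError(
                    f"rule {self.enzyme!r}: clause must constrain P1 and/or P1'"
                )


def _parse_clause(raw: Mapping[str, Mapping[str, str]]) -> Clause:
    clause = {}
    for slot, spec in raw.items():
        if slot not in _SLOT_OFFSETS:
            raise ValidationError(f"unknown window slot {slot!r}")
        (kind, residues), = spec.items()
        if kind not in ("allowed", "forbidden"):
            raise ValidationError(f"slot {slot}: unknown constraint kind {kind!r}")
        clause[slot] = SlotConstraint(kind, frozenset(residues))
    return clause


def load_rules(path: Optional[str] = None) -> dict[str, CleavageRule]:
    """Load the shipped (or a user-supplied) cleavage rule table."""
    if path is None:
        text = resources.files("pepscreen.data").joinpath("cleavage_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    rules = {}
    for name, spec in raw["enzymes"].items():
        rules[name] = CleavageRule(
            enzyme=name,
            clauses=tuple(_parse_clause(c) for c in spec["clauses"]),
            exceptions=tuple(_parse_clause(c) for c in spec.get("exceptions", ())),
        )
    return rules


_RULES: Optional[dict[str, CleavageRule]] = None


def available_enzymes() -> list[str]:
    return sorted(_get_rules())


def _get_rules() -> dict[str, CleavageRule]:
    global _RULES
    if _RULES is None:
        _RULES = load_rules()
    return _RULES


def _resolve(enzyme: str | CleavageRule) -> CleavageRule:
    if isinstance(enzyme, CleavageRule):
        return enzyme
    rules = _get_rules()
    if enzyme not in rules:
        raise ValidationError(
            f"unknown enzyme {enzyme!r}; available: {', '.join(sorted(rules))}"
        )
    return rules[enzyme]


def _clause_matches(sequence: str, bond: int, clause: Clause) -> bool:
    # bond i (1-based) lies between sequence[i-1] and sequence[i]
    for slot, constraint in clause.items():
        pos = bond - 1 + _SLOT_OFFSETS[slot]
        if pos < 0 or pos >= len(sequence):
            # A constrained slot with no residue fails the clause: no phantom
            # residues are invented to satisfy (or escape) a constraint.
            return False
        residue = sequence[pos]
        if constraint.kind == "allowed" and residue not in constraint.residues:
            return False
        if constraint.kind == "forbidden" and residue in constraint.residues:
            return False
    return True


def find_cleavage_sites(sequence: str, enzyme: str | CleavageRule) -> set[int]:
    """Bond indices cut by one enzyme (bond i = between residues i and i+1)."""
    rule = _resolve(enzyme)
    sites = set()
    for bond in range(1, len(sequence)):
        if any(_clause_matches(sequence, bond, c) for c in rule.clauses) and not any(
            _clause_matches(sequence, bond, c) for c in rule.exceptions
        ):
            sites.add(bond)
    return sites


def cut_positions(sequence: str, enzymes: Iterable[str | CleavageRule]) -> set[int]:
    """Union of cut sets over an enzyme set (simultaneous digestion)."""
    sites: set[int] = set()
    for enzyme in enzymes:
        sites |= find_cleavage_sites(sequence, enzyme)
    return sites


@dataclass
class DigestResult:
    """Outcome of digesting one protein: cut set, fragments, survivors."""

    parent_id: str
    cut_positions: set[int]
    fragments: list[PeptideFragment]
    survivors: list[PeptideFragment]


def digest(
    protein: ProteinRecord,
    enzymes: Sequence[str | CleavageRule] = ("pepsin_ph2", "trypsin", "chymotrypsin_low"),
    min_length: int = 9,
    source: Source = Source.IS,
) -> DigestResult:
    """Digest a protein and keep fragments of ``min_length`` or more residues.

    Fragments are the maximal uncut runs between the union of cleavage
    sites; they tile the parent exactly.  The length filter is inclusive
    (a 9-mer survives the default filter).
    """
    seq = protein.sequence
    if not seq:
        raise ValidationError(f"protein {protein.id!r}: empty sequence")
    cuts = cut_positions(seq, enzymes)
    bounds = [0, *sorted(cuts), len(seq)]
    fragments = []
    for left, right in zip(bounds, bounds[1:]):
        start, end = left + 1, right
        fragments.append(
            PeptideFragment(
                parent_id=protein.id,
                start=start,
                end=end,
                sequence=seq[left:right],
                source=source,
                allergen_label=protein.allergen_label,
            )
        )
    survivors = [f for f in fragments if len(f) >= min_length]
    return DigestResult(protein.id, cuts, fragments, survivors)


def is_fixed_point(
    peptide_sequence: str,
    enzymes: Sequence[str | CleavageRule] = ("pepsin_ph2", "trypsin", "chymotrypsin_low"),
) -> bool:
    """True iff re-digesting the isolated peptide produces no internal cut."""
    if not peptide_sequence:
        raise ValidationError("empty peptide sequence")
    return not cut_positions(peptide_sequence, enzymes)
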