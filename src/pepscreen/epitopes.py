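"""Interval matching of peptides against curated IgE / T-cell epitopes and
comparison of peptide sets (e.g. simulated vs in vitro digests).

Matching is reported quantitatively (overlap length and fraction, interval
relation class); no "match" threshold is imposed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .io import PeptideFragment, ValidationError

logger = logging.getLogger(__name__)


class EpitopeKind(str, enum.Enum):
    IgE = "IgE"
    Tcell = "Tcell"


class MatchClass(str, enum.Enum):
    exact = "exact"
    peptide_within_epitope = "peptide_within_epitope"
    epitope_within_peptide = "epitope_within_peptide"
    partial = "partial"
    none = "none"


@dataclass(frozen=True)
class EpitopeRecord:
    """A curated epitope interval on a parent protein."""

    parent_id: str
    kind: EpitopeKind
    start: int
    end: int
    sequence: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"epitope {self.parent_id} {self.start}-{self.end}: start > end"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class EpitopeMatch:
    peptide: PeptideFragment
    epitope: EpitopeRecord
    overlap_length: int
    overlap_fraction_of_peptide: float
    match_class: MatchClass


def _interval_relation(ps: int, pe: int, es: int, ee: int) -> MatchClass:
    if ps == es and pe == ee:
        return MatchClass.exact
    if es <= ps and pe <= ee:
        return MatchClass.peptide_within_epitope
    if ps <= es and ee <= pe:
        return MatchClass.epitope_within_peptide
    return MatchClass.partial


def match_peptide_epitope(peptide: PeptideFragment, epitope: EpitopeRecord) -> EpitopeMatch:
    """Quantify the interval overlap between one peptide and one epitope."""
    overlap = max(0, min(peptide.end, epitope.end) - max(peptide.start, epitope.start) + 1)
    if overlap == 0:
        cls = MatchClass.none
    else:
        cls = _interval_relation(peptide.start, peptide.end, epitope.start, epitope.end)
    return EpitopeMatch(
        peptide=peptide,
        epitope=epitope,
        overlap_length=overlap,
        overlap_fraction_of_peptide=overlap / peptide.span,
        match_class=cls,
    )


def map_peptide_to_epitopes(
    peptide: PeptideFragment, epitope_catalog: Iterable[EpitopeRecord]
) -> list[EpitopeMatch]:
    """All epitopes overlapping the peptide by at least one residue.

    Epitopes on a different parent are skipped with a logged warning.
    Matches are sorted by descending overlap length, ties by epitope start.
    """
    matches = []
    for epitope in epitope_catalog:
        if epitope.parent_id != peptide.parent_id:
            logger.warning(
                "skipping epitope %s %d-%d: parent differs from peptide parent %s",
                epitope.parent_id, epitope.start, epitope.end, peptide.parent_id,
            )
            continue
        match = match_peptide_epitope(peptide, epitope)
        if match.overlap_length >= 1:
            matches.append(match)
    matches.sort(key=lambda m: (-m.overlap_length, m.epitope.start))
    return matches


@dataclass
class SetComparison:
    """Pairwise relations between two peptide sets.

    Pair categories are mutually exclusive with precedence
    identical > containment > overlapping.  ``identical`` pairs share the
    exact sequence string; ``containment`` pairs have one sequence a strict
    substring of the other; ``overlapping`` pairs overlap in coordinates on
    the same parent without a substring relation.
    """

    identical: list[tuple[PeptideFragment, PeptideFragment]]
    containment: list[tuple[PeptideFragment, PeptideFragment]]
    overlapping: list[tuple[PeptideFragment, PeptideFragment]]


def compare_peptide_sets(
    set_a: Iterable[PeptideFragment], set_b: Iterable[PeptideFragment]
) -> SetComparison:
    identical, containment, overlapping = [], [], []
    for a in set_a:
        for b in set_b:
            if a.sequence == b.sequence:
                identical.append((a, b))
            elif a.sequence in b.sequence or b.sequence in a.sequence:
                containment.append((a, b))
            elif (
                a.parent_id == b.parent_id
                and min(a.end, b.end) - max(a.start, b.start) + 1 > 0
            ):
                overlapping.append((a, b))
    return SetComparison(identical, containment, overlapping)


EPITOPE_COLUMNS = ["protein_id", "kind", "start", "end", "sequence", "citation"]


def read_epitope_tsv(path: str | Path) -> list[EpitopeRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(EPITOPE_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise ValidationError(f"epitope TSV {path}: missing columns {sorted(missing)}")
    return [
        EpitopeRecord(
            parent_id=row.protein_id,
            kind=EpitopeKind(row.kind),
            start=int(row.start),
            end=int(row.end),
            sequence=str(getattr(row, "sequence", "") or ""),
            citation=str(getattr(row, "citation", "") or ""),
        )
        for row in frame.itertuples(index=False)
    ]


def matches_to_frame(matches: Iterable[EpitopeMatch]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": m.peptide.parent_id,
            "peptide": m.peptide.sequence,
            "peptide_start": m.peptide.start,
            "peptide_end": m.peptide.end,
            "epitope_kind": m.epitope.kind.value,
            "epitope_start": m.epitope.start,
            "epitope_end": m.epitope.end,
            "overlap_length": m.overlap_length,
            "overlap_fraction_of_peptide": m.overlap_fraction_of_peptide,
            "match_class": m.match_class.value,
        }
        for m in matches
    ]
    return pd.DataFrame(rows)
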