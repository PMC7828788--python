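"""Domain types, FASTA/TSV readers and writers, and screening configuration.

Coordinates are 1-based and inclusive on the precursor (signal-peptide
containing) protein sequence throughout the package.  Validation *reports*
coordinate/sequence mismatches instead of rejecting them, because curated
peptide tables from the literature routinely contain such mismatches and
must still load.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

PEPTIDE_COLUMNS = ["protein_id", "allergen_label", "start", "end", "sequence", "source", "flag"]


class Source(str, enum.Enum):
    """Provenance of a peptide: simulated (IS) or in vitro (IV) digestion."""

    IS = "IS"
    IV = "IV"


class ValidationError(ValueError):
    """Raised when an input file violates a hard schema constraint."""


@dataclass(frozen=True)
class ProteinRecord:
    """An input protein with identity, allergen label and 1-based sequence."""

    id: str
    name: str = ""
    allergen_label: Optional[str] = None
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = [(i + 1, aa) for i, aa in enumerate(self.sequence) if aa not in AMINO_ACIDS]
        if bad:
            pos, aa = bad[0]
            raise ValidationError(
                f"protein {self.id!r}: non-amino-acid character {aa!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start``..``end`` (1-based, inclusive)."""
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class PeptideFragment:
    """A digestion- or MS-derived peptide located on its parent protein."""

    parent_id: str
    start: int
    end: int
    sequence: str
    source: Source = Source.IS
    allergen_label: Optional[str] = None
    flag: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class AllelePanel:
    """A named set of MHC-II alleles with an immunological role."""

    name: str
    alleles: tuple[str, ...]
    role: str  # "susceptibility" or "protection"

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValidationError(f"panel {self.name!r}: empty allele list")


def default_panels() -> dict[str, AllelePanel]:
    """Milk-allergy susceptibility and protection panels.

    DRB1*01:01, DQ7 (DQA1*05:01/DQB1*03:01) and DQ8 (DQA1*03:01/DQB1*03:02)
    are associated with susceptibility to cow's-milk allergy; DRB1*03:01,
    DRB1*14:19 and DRB1*14:21 appear protective.
    """
    return {
        "susceptibility": AllelePanel(
            "susceptibility", ("DRB1*01:01", "DQ7", "DQ8"), "susceptibility"
        ),
        "protection": AllelePanel(
            "protection", ("DRB1*03:01", "DRB1*14:19", "DRB1*14:21"), "protection"
        ),
    }


@dataclass
class ScreenConfig:
    """Tunable thresholds of the screening pipeline.

    pIC50 thresholds follow the EpiTOP3 convention (strong binder above 6.3,
    weak binder above 5.3); IC50 tiers follow the IEDB convention (high
    below 50 nM, intermediate below 500 nM, low below 5000 nM).
    """

    enzyme_set: tuple[str, ...] = ("pepsin_ph2", "trypsin", "chymotrypsin_low")
    min_peptide_length: int = 9
    pic50_strong: float = 6.3
    pic50_weak: float = 5.3
    ic50_high_nM: float = 50.0
    ic50_intermediate_nM: float = 500.0
    ic50_low_nM: float = 5000.0
    svm_threshold: float = 0.2
    window_lengths: tuple[int, ...] = (9, 15)
    mascot_cutoff: float = 32.0
    normalization_scheme: str = "panel-max"
    verdict_margin: float = 0.1
    verdict_floor: float = 0.01
    locus_sizes: dict = field(default_factory=lambda: {"DRB1": 12, "DQ": 5, "DP": 7})
    panels: dict = field(default_factory=default_panels)

    def __post_init__(self) -> None:
        if self.min_peptide_length < 1:
            raise ValidationError("min_peptide_length must be >= 1")
        if not self.pic50_strong > self.pic50_weak:
            raise ValidationError("pic50_strong must exceed pic50_weak")
        if not self.ic50_high_nM < self.ic50_intermediate_nM < self.ic50_low_nM:
            raise ValidationError("IC50 tier bounds must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("enzyme_set", "window_lengths"):
            if key in data:
                data[key] = tuple(data[key])
        if "panels" in data:
            data["panels"] = {
                name: AllelePanel(name, tuple(spec["alleles"]), spec.get("role", name))
                for name, spec in data["panels"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["enzyme_set"] = list(self.enzyme_set)
        data["window_lengths"] = list(self.window_lengths)
        data["panels"] = {
            name: {"alleles": list(panel.alleles), "role": panel.role}
            for name, panel in self.panels.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA, preserving order and uppercasing.

    The allergen label is recovered from an ``allergen=...`` token in the
    description when present.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = None
        for part in rec.description.split("|"):
            part = part.strip()
            if part.startswith("allergen="):
                label = part[len("allergen=") :].strip()
        records.append(
            ProteinRecord(
                id=rec.id,
                name=rec.description,
                allergen_label=label,
                sequence=str(rec.seq).upper(),
            )
        )
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.allergen_label:
                header += f" {rec.name} | allergen={rec.allergen_label}"
            elif rec.name:
                header += f" {rec.name}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def validate_fragment(
    fragment: PeptideFragment, parent: Optional[ProteinRecord] = None
) -> list[str]:
    """Report every internal inconsistency of a peptide fragment.

    Returns an empty list iff coordinates are ordered, the sequence length
    matches the span, and (when the parent is supplied) the sequence equals
    the parent subsequence.  Pure reporting: the fragment is never modified.
    """
    reports = []
    if fragment.start < 1:
        reports.append(f"start {fragment.start} < 1")
    if fragment.start > fragment.end:
        reports.append(f"interval ordering violated: start {fragment.start} > end {fragment.end}")
        return reports
    if len(fragment.sequence) != fragment.span:
        reports.append(
            f"length/span mismatch: {len(fragment.sequence)} residues vs span "
            f"{fragment.span} ({fragment.start}-{fragment.end})"
        )
    if parent is not None:
        if parent.id != fragment.parent_id:
            reports.append(
                f"parent mismatch: fragment refers to {fragment.parent_id!r}, got {parent.id!r}"
            )
        elif fragment.end > parent.length:
            reports.append(f"end {fragment.end} exceeds parent length {parent.length}")
        elif parent.subsequence(fragment.start, fragment.end) != fragment.sequence:
            reports.append(
                f"sequence differs from parent residues {fragment.start}-{fragment.end}"
            )
    return reports


def peptides_to_frame(peptides: Iterable[PeptideFragment]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": p.parent_id,
            "allergen_label": p.allergen_label or "",
            "start": p.start,
            "end": p.end,
            "sequence": p.sequence,
            "source": p.source.value,
            "flag": p.flag,
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def frame_to_peptides(frame: pd.DataFrame) -> list[PeptideFragment]:
    peptides = []
    for row in frame.itertuples(index=False):
        label = getattr(row, "allergen_label", "") or ""
        peptides.append(
            PeptideFragment(
                parent_id=row.protein_id,
                start=int(row.start),
                end=int(row.end),
                sequence=row.sequence,
                source=Source(row.source),
                allergen_label=label or None,
                flag=str(getattr(row, "flag", "") or ""),
            )
        )
    return peptides


def write_peptide_tsv(peptides: Iterable[PeptideFragment], path: str | Path) -> None:
    peptides_to_frame(peptides).to_csv(path, sep="\t", index=False)


def read_peptide_tsv(path: str | Path) -> list[PeptideFragment]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"flag": str})
    missing = set(PEPTIDE_COLUMNS[:-1]) - set(frame.columns)
    if missing:
        raise ValidationError(f"peptide TSV {path}: missing columns {sorted(missing)}")
    return frame_to_peptides(frame)
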