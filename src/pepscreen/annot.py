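"""Ingestion and aggregation of cytokine-induction predictions and
bioactivity annotations.

Predictor outputs (SVM decision scores from IL-4 / IFN-gamma / IL-10
induction models, bioactivity database hits) are treated as opaque
evidence: they are validated, stored and aggregated, never recomputed.
A window is *inducing* when its score is strictly greater than the
threshold (default 0.2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import ValidationError


class Cytokine(str, enum.Enum):
    IL4 = "IL4"
    IFNG = "IFNG"
    IL10 = "IL10"


class BioFunction(str, enum.Enum):
    immunomodulatory = "immunomodulatory"
    antimicrobial = "antimicrobial"
    anti_inflammatory = "anti_inflammatory"
    il10_inducer = "il10_inducer"


@dataclass(frozen=True)
class CytokineRecord:
    """Summary of a cytokine-induction predictor run on one peptide."""

    peptide_id: str
    cytokine: Cytokine
    n_inducing: int
    score_min: Optional[float] = None
    score_max: Optional[float] = None
    window_length: int = 9
    threshold: float = 0.2
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_inducing < 0:
            raise ValidationError(f"{self.peptide_id}/{self.cytokine}: negative n_inducing")
        if self.n_inducing > 0:
            if self.score_min is None or self.score_max is None:
                raise ValidationError(
                    f"{self.peptide_id}/{self.cytokine}: inducing windows without scores"
                )
            if self.score_min > self.score_max:
                raise ValidationError(
                    f"{self.peptide_id}/{self.cytokine}: score_min > score_max"
                )


@dataclass(frozen=True)
class BioactivityTag:
    """A proven bioactive function carried by a peptide."""

    peptide_id: str
    function: BioFunction
    n_sequences: int
    evidence: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValidationError(f"{self.peptide_id}/{self.function}: n_sequences < 1")


def enumerate_windows(sequence: str, window_length: int) -> list[tuple[int, str]]:
    """All overlapping windows of the given length with 1-based offsets.

    A window longer than the sequence yields an empty list (not an error).
    """
    if window_length < 1:
        raise ValidationError(f"window_length must be >= 1, got {window_length}")
    return [
        (i + 1, sequence[i : i + window_length])
        for i in range(len(sequence) - window_length + 1)
    ]


def summarize_scores(
    peptide_id: str,
    cytokine: Cytokine,
    window_scores: Sequence[float],
    threshold: float = 0.2,
    window_length: int = 9,
) -> CytokineRecord:
    """Collapse per-window predictor scores to an induction summary.

    ``n_inducing`` counts scores strictly above the threshold; the score
    range is taken over inducing windows only.  Invariant to window order.
    """
    inducing = [s for s in window_scores if s > threshold]
    return CytokineRecord(
        peptide_id=peptide_id,
        cytokine=cytokine,
        n_inducing=len(inducing),
        score_min=min(inducing) if inducing else None,
        score_max=max(inducing) if inducing else None,
        window_length=window_length,
        threshold=threshold,
    )


def check_window_consistency(
    record: CytokineRecord, peptide_sequence: str
) -> list[str]:
    """Flag summaries reporting more inducing windows than the peptide has.

    Published summary tables contain such rows (the counting unit the
    upstream predictor used is not always the stated window length), so the
    checker reports rather than fails.
    """
    available = max(0, len(peptide_sequence) - record.window_length + 1)
    if record.n_inducing > available:
        return [
            f"{record.peptide_id}/{record.cytokine.value}: {record.n_inducing} inducing "
            f"windows reported but only {available} windows of length "
            f"{record.window_length} exist"
        ]
    return []


def count_by_function(tags: Iterable[BioactivityTag], function: BioFunction | str) -> int:
    """Number of distinct peptides carrying the given function."""
    function = BioFunction(function)
    return len({t.peptide_id for t in tags if t.function is function})


CYTOKINE_COLUMNS = ["peptide_id", "cytokine", "n_inducing", "score_min", "score_max", "window_length"]
BIOACTIVITY_COLUMNS = ["peptide_id", "function", "n_sequences", "evidence"]


def read_cytokine_tsv(path: str | Path, threshold: float = 0.2) -> list[CytokineRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(CYTOKINE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"cytokine TSV {path}: missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        n = int(row.n_inducing)
        records.append(
            CytokineRecord(
                peptide_id=row.peptide_id,
                cytokine=Cytokine(row.cytokine),
                n_inducing=n,
                score_min=float(row.score_min) if n > 0 else None,
                score_max=float(row.score_max) if n > 0 else None,
                window_length=int(row.window_length),
                threshold=threshold,
                source=str(getattr(row, "source", "") or ""),
            )
        )
    return records


def read_bioactivity_tsv(path: str | Path) -> list[BioactivityTag]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(BIOACTIVITY_COLUMNS[:3]) - set(frame.columns)
    if missing:
        raise ValidationError(f"bioactivity TSV {path}: missing columns {sorted(missing)}")
    return [
        BioactivityTag(
            peptide_id=row.peptide_id,
            function=BioFunction(row.function),
            n_sequences=int(row.n_sequences),
            evidence=str(getattr(row, "evidence", "") or ""),
            source=str(getattr(row, "source", "") or ""),
        )
        for row in frame.itertuples(index=False)
    ]
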