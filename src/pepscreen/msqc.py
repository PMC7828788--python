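"""MS identification summaries and replicate-homogeneity checking.

Identification summaries (Mascot score, sequence coverage, mass, protein
abundance index) are ingested per replicate; the score cut-off filter is
inclusive (score >= cutoff is retained, the conventional Mascot reading of
a significance threshold).  Replicate homogeneity is assessed with
Manhattan distances on the (score, abundance index) plane for keys present
in every replicate; because the two dimensions live on incomparable scales
they are standardized by their pooled standard deviation by default (a raw
mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError


@dataclass(frozen=True)
class MSIdentification:
    accession: str
    mascot_score: float
    coverage_percent: float
    mass_da: float
    abundance_index: float
    replicate: str = "r1"
    protein_name: str = ""

    def __post_init__(self) -> None:
        if self.mascot_score < 0:
            raise ValidationError(f"{self.accession}: negative Mascot score")
        if not 0 <= self.coverage_percent <= 100:
            raise ValidationError(f"{self.accession}: coverage outside [0, 100]")


def read_ms_tsv(path: str | Path, replicate: Optional[str] = None) -> list[MSIdentification]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"accession", "score", "pai"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"MS TSV {path}: missing columns {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            MSIdentification(
                accession=row.accession,
                mascot_score=float(row.score),
                coverage_percent=float(getattr(row, "coverage_percent", 0.0)),
                mass_da=float(getattr(row, "mass_da", 0.0)),
                abundance_index=float(row.pai),
                replicate=replicate or str(getattr(row, "replicate", "r1") or "r1"),
                protein_name=str(getattr(row, "protein_name", "") or ""),
            )
        )
    return out


def filter_identifications(
    identifications: Iterable[MSIdentification], cutoff: float = 32.0
) -> list[MSIdentification]:
    """Retain identifications whose score meets the cutoff (inclusive)."""
    return [i for i in identifications if i.mascot_score >= cutoff]


@dataclass
class HomogeneityResult:
    """Pairwise replicate distances per key plus the excluded keys."""

    distances: pd.DataFrame  # columns: key, replicate_a, replicate_b, distance
    summary: dict  # min, max, mean over all pairwise distances
    heterogeneous_keys: list[str]  # keys whose min pairwise distance exceeds the flag level
    excluded_keys: list[str]  # keys absent from at least one replicate


def manhattan_homogeneity(
    replicates: Sequence[Sequence[MSIdentification]],
    standardize: bool = True,
    flag_level: Optional[float] = None,
) -> HomogeneityResult:
    """Manhattan-distance homogeneity of identification replicates.

    distance(a, b) = |score_a - score_b| + |pai_a - pai_b|, computed per
    key over every replicate pair.  With ``standardize`` each dimension is
    first divided by its pooled standard deviation across all replicates.
    Keys absent from any replicate are excluded and listed.  Keys whose
    minimum pairwise distance exceeds ``flag_level`` (default: the mean of
    all pairwise distances) are flagged heterogeneous.
    """
    if len(replicates) < 2:
        raise ValidationError("homogeneity analysis requires >= 2 replicates")
    tables = []
    for idx, rep in enumerate(replicates):
        name = rep[0].replicate if rep else f"r{idx + 1}"
        tables.append({i.accession: i for i in rep})
        if len(tables[-1]) != len(rep):
            raise ValidationError(f"replicate {name}: duplicate accessions")
    all_keys = sorted(set().union(*tables))
    common = [k for k in all_keys if all(k in t for t in tables)]
    excluded = [k for k in all_keys if k not in common]

    scores = np.array([[t[k].mascot_score for t in tables] for k in common], dtype=float)
    pais = np.array([[t[k].abundance_index for t in tables] for k in common], dtype=float)
    if standardize and common:
        s_sd = scores.std(ddof=1) if scores.size > 1 else 0.0
        p_sd = pais.std(ddof=1) if pais.size > 1 else 0.0
        scores = scores / s_sd if s_sd > 0 else scores * 0.0
        pais = pais / p_sd if p_sd > 0 else pais * 0.0

    rep_names = [
        rep[0].replicate if rep else f"r{i + 1}" for i, rep in enumerate(replicates)
    ]
    rows = []
    for ki, key in enumerate(common):
        for a, b in combinations(range(len(tables)), 2):
            d = abs(scores[ki, a] - scores[ki, b]) + abs(pais[ki, a] - pais[ki, b])
            rows.append(
                {"key": key, "replicate_a": rep_names[a], "replicate_b": rep_names[b],
                 "distance": d}
            )
    frame = pd.DataFrame(rows, columns=["key", "replicate_a", "replicate_b", "distance"])
    if len(frame):
        summary = {
            "min": float(frame.distance.min()),
            "max": float(frame.distance.max()),
            "mean": float(frame.distance.mean()),
        }
    else:
        summary = {"min": float("nan"), "max": float("nan"), "mean": float("nan")}
    level = flag_level if flag_level is not None else summary["mean"]
    heterogeneous = []
    if len(frame):
        per_key_min = frame.groupby("key").distance.min()
        heterogeneous = sorted(per_key_min[per_key_min > level].index)
    return HomogeneityResult(frame, summary, heterogeneous, excluded)
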