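"""Integrated 16-factor radar-polygon evaluation of peptide potential.

Every peptide is summarized by sixteen factors on axes at equal angles
2*pi/16, in a fixed order that is part of the public contract:

  1 DRB1-weak, 2 DQ-weak, 3 DP-weak,
  4 DRB1-strong, 5 DQ-strong, 6 DP-strong,
  7 strong binders in the allergy-susceptibility allele panel,
  8 weak binders in the allergy-susceptibility panel,
  9 IL-4 induction score, 10 IFN-gamma induction score,
  11 strong binders in the tolerance (protection) panel,
  12 weak binders in the tolerance panel,
  13 IL-10 induction score,
  14 immunomodulatory, 15 antimicrobial, 16 anti-inflammatory (binary).

Factors 4-9 form the pro-allergenic sector and 10-16 the tolerogenic
sector; factors 1-3 (weak binding across loci) may matter in both reaction
types and therefore enter only the total (cyclic) polygon area, never a
sector.  IFN-gamma sits in the tolerogenic sector by the adopted factor
order although its pro-inflammatory reading is equally defensible; reports
should interpret factor 10 in both contexts.

The polygon area over normalized axes r_1..r_16 is a fan of triangles:
total = 1/2*sin(2*pi/16) * sum_k r_k*r_{k+1} (cyclic), and a sector over a
contiguous factor range is the open chain of origin-anchored triangles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annot import BioactivityTag, BioFunction, Cytokine, CytokineRecord
from .binding import LocusCounts, PanelSummary
from .io import PeptideFragment, ScreenConfig, ValidationError

N_FACTORS = 16
SECTOR_ANGLE = 2.0 * math.pi / N_FACTORS

FACTOR_NAMES = (
    "drb1_weak", "dq_weak", "dp_weak",
    "drb1_strong", "dq_strong", "dp_strong",
    "allergy_panel_strong", "allergy_panel_weak",
    "il4", "ifng",
    "tolerance_panel_strong", "tolerance_panel_weak",
    "il10",
    "immunomodulatory", "antimicrobial", "anti_inflammatory",
)

ALLERGENIC_RANGE = (4, 9)   # 1-based, inclusive
TOLEROGENIC_RANGE = (10, 16)

_SCORE_FACTORS = (9, 10, 13)   # SVM-score axes, min-max scaled over the batch
_BINARY_FACTORS = (14, 15, 16)


class Verdict(str, enum.Enum):
    allergenic_dominant = "allergenic_dominant"
    tolerogenic_dominant = "tolerogenic_dominant"
    dual = "dual"
    inert = "inert"


@dataclass
class FeatureVector16:
    """Raw and normalized 16-factor description of one peptide."""

    peptide_id: str
    raw: np.ndarray
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (N_FACTORS,):
            raise ValidationError(f"feature vector must have {N_FACTORS} entries")


@dataclass
class PotentialScore:
    peptide_id: str
    allergenic_area: float
    tolerogenic_area: float
    total_area: float
    verdict: Verdict


_CYTOKINE_FACTOR = {Cytokine.IL4: 9, Cytokine.IFNG: 10, Cytokine.IL10: 13}
_FUNCTION_FACTOR = {
    BioFunction.immunomodulatory: 14,
    BioFunction.antimicrobial: 15,
    BioFunction.anti_inflammatory: 16,
}


def build_features(
    peptide: PeptideFragment | str,
    binder_counts: Optional[LocusCounts] = None,
    panel_summaries: Optional[Mapping[str, PanelSummary]] = None,
    cytokine_records: Iterable[CytokineRecord] = (),
    tags: Iterable[BioactivityTag] = (),
) -> FeatureVector16:
    """Assemble the raw 16-factor vector from upstream summaries.

    Missing evidence maps to a raw 0.  Cytokine factors carry the maximum
    inducing-window score (0 when nothing induces); bioactivity factors are
    binary presence.  IL-10 evidence can come either from an IL10 cytokine
    record or from an ``il10_inducer`` bioactivity tag (database evidence);
    the score-bearing record wins when both exist.
    """
    peptide_id = peptide.sequence if isinstance(peptide, PeptideFragment) else peptide
    raw = np.zeros(N_FACTORS)
    if binder_counts is not None:
        for i, locus in enumerate(("DRB1", "DQ", "DP")):
            raw[i] = binder_counts.weak[locus]
            raw[i + 3] = binder_counts.strong[locus]
    if panel_summaries is not None:
        sus = panel_summaries.get("susceptibility")
        if sus is not None:
            raw[6], raw[7] = sus.n_strong, sus.n_weak
        prot = panel_summaries.get("protection")
        if prot is not None:
            raw[10], raw[11] = prot.n_strong, prot.n_weak
    for rec in cytokine_records:
        if rec.peptide_id != peptide_id:
            continue
        idx = _CYTOKINE_FACTOR[rec.cytokine] - 1
        raw[idx] = rec.score_max if rec.n_inducing > 0 else 0.0
    for tag in tags:
        if tag.peptide_id != peptide_id:
            continue
        if tag.function is BioFunction.il10_inducer:
            if raw[12] == 0.0:
                raw[12] = 1.0
        else:
            raw[_FUNCTION_FACTOR[tag.function] - 1] = 1.0
    return FeatureVector16(peptide_id, raw)


def normalize(
    vectors: Sequence[FeatureVector16],
    scheme: str = "panel-max",
    config: Optional[ScreenConfig] = None,
) -> list[FeatureVector16]:
    """Normalize raw factor values to [0, 1] in place and return the batch.

    ``panel-max`` (default): binder-count factors are divided by the fixed
    panel sizes (12 DRB1, 5 DQ, 7 DP alleles; allele panels of 3); SVM-score
    factors are floored at 0 and divided by the batch maximum; binary
    factors pass through.  ``batch-max``: every factor is divided by its
    batch maximum (an all-zero column stays zero).
    """
    if not vectors:
        raise ValidationError("normalize requires at least one vector")
    cfg = config or ScreenConfig()
    matrix = np.stack([v.raw for v in vectors]).astype(float)
    matrix = np.clip(matrix, 0.0, None)
    if scheme == "panel-max":
        locus_max = [cfg.locus_sizes[l] for l in ("DRB1", "DQ", "DP")]
        denom = np.ones(N_FACTORS)
        denom[0:3] = locus_max
        denom[3:6] = locus_max
        denom[6] = denom[7] = len(cfg.panels["susceptibility"].alleles)
        denom[10] = denom[11] = len(cfg.panels["protection"].alleles)
        for idx in _SCORE_FACTORS:
            col_max = matrix[:, idx - 1].max()
            denom[idx - 1] = col_max if col_max > 0 else 1.0
        normalized = matrix / denom
    elif scheme == "batch-max":
        col_max = matrix.max(axis=0)
        safe = np.where(col_max > 0, col_max, 1.0)
        normalized = matrix / safe
    else:
        raise ValidationError(f"unknown normalization scheme {scheme!r}")
    normalized = np.clip(normalized, 0.0, 1.0)
    for vec, row in zip(vectors, normalized):
        vec.normalized = row
    return list(vectors)


def radar_area(
    normalized_vector: Sequence[float],
    factor_range: Optional[tuple[int, int]] = None,
) -> float:
    """Area of the radar polygon (or of one contiguous sector chain).

    With no range, the full cyclic polygon over all 16 axes; with a range
    (i, j), 1-based inclusive, the open chain of origin-anchored triangles
    between consecutive axes i..j.  All axes at equal angles 2*pi/16.
    """
    r = np.asarray(normalized_vector, dtype=float)
    if r.shape != (N_FACTORS,):
        raise ValidationError(f"radar_area expects {N_FACTORS} values, got {r.shape}")
    half_sin = 0.5 * math.sin(SECTOR_ANGLE)
    if factor_range is None:
        return half_sin * float(np.dot(r, np.roll(r, -1)))
    i, j = factor_range
    if not (1 <= i <= j <= N_FACTORS):
        raise ValidationError(f"invalid factor range {factor_range}")
    return half_sin * float(np.dot(r[i - 1 : j - 1], r[i : j]))


def verdict(
    allergenic_area: float,
    tolerogenic_area: float,
    margin: float = 0.1,
    floor: float = 0.01,
) -> Verdict:
    """Label the balance of the two sector areas.

    Dominance requires one sector to exceed the other by the relative
    margin; both sectors at or below the floor is inert; two comparably
    sized sectors above the floor are dual.
    """
    if allergenic_area <= floor and tolerogenic_area <= floor:
        return Verdict.inert
    if allergenic_area > tolerogenic_area * (1.0 + margin):
        return Verdict.allergenic_dominant
    if tolerogenic_area > allergenic_area * (1.0 + margin):
        return Verdict.tolerogenic_dominant
    return Verdict.dual


def score_vector(
    vector: FeatureVector16, config: Optional[ScreenConfig] = None
) -> PotentialScore:
    """Sector areas, total area and verdict for one normalized vector."""
    if vector.normalized is None:
        raise ValidationError("vector must be normalized before scoring")
    cfg = config or ScreenConfig()
    a = radar_area(vector.normalized, ALLERGENIC_RANGE)
    t = radar_area(vector.normalized, TOLEROGENIC_RANGE)
    total = radar_area(vector.normalized)
    return PotentialScore(
        vector.peptide_id, a, t, total,
        verdict(a, t, cfg.verdict_margin, cfg.verdict_floor),
    )


def scores_to_frame(
    vectors: Sequence[FeatureVector16], config: Optional[ScreenConfig] = None
) -> pd.DataFrame:
    """Score TSV layout: raw and normalized factors, areas, verdict."""
    rows = []
    for vec in vectors:
        score = score_vector(vec, config)
        row = {"peptide_id": vec.peptide_id}
        row.update({f"raw_{name}": vec.raw[i] for i, name in enumerate(FACTOR_NAMES)})
        row.update(
            {f"norm_{name}": vec.normalized[i] for i, name in enumerate(FACTOR_NAMES)}
        )
        row["allergenic_area"] = score.allergenic_area
        row["tolerogenic_area"] = score.tolerogenic_area
        row["total_area"] = score.total_area
        row["verdict"] = score.verdict.value
        rows.append(row)
    return pd.DataFrame(rows)


def plot_radar(vector: FeatureVector16, path: str, title: str = "") -> None:
    """Export a radar chart of one normalized vector (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if vector.normalized is None:
        raise ValidationError("vector must be normalized before plotting")
    angles = np.arange(N_FACTORS) * SECTOR_ANGLE
    values = np.asarray(vector.normalized)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    closed_angles = np.append(angles, angles[0])
    closed_values = np.append(values, values[0])
    ax.plot(closed_angles, closed_values, lw=1.2)
    ax.fill(closed_angles, closed_values, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels([str(i + 1) for i in range(N_FACTORS)])
    ax.set_ylim(0, 1)
    ax.set_title(title or vector.peptide_id)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
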