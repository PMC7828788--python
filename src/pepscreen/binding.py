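"""MHC class II binding-strength classification and allele-panel summaries.

Affinities arrive either as pIC50 (negative decadic logarithm of IC50 in
molar units) or as IC50 in nanomolar; the scales interconvert via
``pIC50 = 9 - log10(IC50_nM)``.  Binder classes follow the EpiTOP3
convention (strong: pIC50 > 6.3; weak: 5.3 < pIC50 <= 6.3) and affinity
tiers the IEDB convention (high: IC50 < 50 nM; intermediate: < 500 nM;
low: < 5000 nM).  The pIC50 rule is authoritative when both scales are
supplied: note 10**(9-6.3) = 501.19 nM, so IC50 values inside
(500, 501.19) nM classify as strong although the printed "< 500 nM"
shorthand would call them weak.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .io import AllelePanel, ScreenConfig, ValidationError

logger = logging.getLogger(__name__)

LOCI = ("DRB1", "DQ", "DP")


class BinderClass(str, enum.Enum):
    strong = "strong"
    weak = "weak"
    none = "none"


class AffinityTier(str, enum.Enum):
    high = "high"
    intermediate = "intermediate"
    low = "low"
    none = "none"


def pic50_to_ic50_nM(pic50: float) -> float:
    return 10.0 ** (9.0 - pic50)


def ic50_nM_to_pic50(ic50_nM: float) -> float:
    if ic50_nM <= 0:
        raise ValidationError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


@dataclass(frozen=True)
class AffinityMeasurement:
    """One peptide x allele affinity, on either scale.

    ``censored`` marks table entries printed as a bound (e.g. ">5000" nM);
    a censored low-affinity value always classifies as non-binder.
    pIC50 inputs printed with a spurious leading minus are read as positive
    (logged on ingestion by the TSV reader).
    """

    peptide_id: str
    allele: str
    locus: str
    pic50: Optional[float] = None
    ic50_nM: Optional[float] = None
    censored: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.pic50 is None and self.ic50_nM is None:
            raise ValidationError(
                f"{self.peptide_id} x {self.allele}: no affinity value on either scale"
            )
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ValidationError(
                f"{self.peptide_id} x {self.allele}: non-positive IC50 {self.ic50_nM}"
            )
        if self.pic50 is not None and not math.isfinite(self.pic50):
            raise ValidationError(f"{self.peptide_id} x {self.allele}: non-finite pIC50")

    @property
    def pic50_value(self) -> float:
        if self.pic50 is not None:
            return self.pic50
        return ic50_nM_to_pic50(self.ic50_nM)

    @property
    def ic50_value_nM(self) -> float:
        if self.ic50_nM is not None:
            return self.ic50_nM
        return pic50_to_ic50_nM(self.pic50)


@dataclass(frozen=True)
class BinderCall:
    binder_class: BinderClass
    affinity_tier: AffinityTier


def classify_affinity(
    measurement: AffinityMeasurement, config: Optional[ScreenConfig] = None
) -> BinderCall:
    """Classify one measurement on both the pIC50 and the IC50 scale.

    Half-open bins, upper bound excluded on the nM scale ("<50", "<500",
    "<5000"); IC50 at or above 5000 nM, and censored ">5000" entries, are
    non-binders on the tier scale.
    """
    cfg = config or ScreenConfig()
    if measurement.censored:
        return BinderCall(BinderClass.none, AffinityTier.none)
    pic50 = measurement.pic50_value
    if pic50 > cfg.pic50_strong:
        binder = BinderClass.strong
    elif pic50 > cfg.pic50_weak:
        binder = BinderClass.weak
    else:
        binder = BinderClass.none
    ic50 = measurement.ic50_value_nM
    if ic50 < cfg.ic50_high_nM:
        tier = AffinityTier.high
    elif ic50 < cfg.ic50_intermediate_nM:
        tier = AffinityTier.intermediate
    elif ic50 < cfg.ic50_low_nM:
        tier = AffinityTier.low
    else:
        tier = AffinityTier.none
    return BinderCall(binder, tier)


@dataclass
class LocusCounts:
    """Per-locus strong/weak binder counts for one peptide."""

    peptide_id: str
    strong: dict[str, int]
    weak: dict[str, int]

    @property
    def total_binders(self) -> int:
        return sum(self.strong.values()) + sum(self.weak.values())

    @classmethod
    def from_row(cls, peptide_id: str, row: Mapping[str, int]) -> "LocusCounts":
        return cls(
            peptide_id=peptide_id,
            strong={loc: int(row[f"strong_{loc.lower()}"]) for loc in LOCI},
            weak={loc: int(row[f"weak_{loc.lower()}"]) for loc in LOCI},
        )


def _check_duplicates(measurements: Iterable[AffinityMeasurement]) -> None:
    seen = set()
    for m in measurements:
        key = (m.peptide_id, m.allele)
        if key in seen:
            raise ValidationError(f"duplicate measurement for peptide x allele {key}")
        seen.add(key)


def locus_binder_counts(
    peptide_id: str,
    measurements: Iterable[AffinityMeasurement],
    config: Optional[ScreenConfig] = None,
) -> LocusCounts:
    """Count strong and weak binder alleles per locus for one peptide.

    Each allele contributes to exactly one class (strong, weak, or none), so
    strong + weak + none equals the number of measured alleles per locus.
    """
    rows = [m for m in measurements if m.peptide_id == peptide_id]
    _check_duplicates(rows)
    strong = dict.fromkeys(LOCI, 0)
    weak = dict.fromkeys(LOCI, 0)
    for m in rows:
        if m.locus not in LOCI:
            raise ValidationError(f"unknown locus {m.locus!r} for allele {m.allele!r}")
        call = classify_affinity(m, config).binder_class
        if call is BinderClass.strong:
            strong[m.locus] += 1
        elif call is BinderClass.weak:
            weak[m.locus] += 1
    return LocusCounts(peptide_id, strong, weak)


@dataclass
class PanelSummary:
    """Binder counts and best affinity within one allele panel."""

    panel: AllelePanel
    n_strong: int
    n_weak: int
    best_ic50_nM: Optional[float]  # minimum IC50 == maximum pIC50; None if no data
    best_tier: AffinityTier
    missing_alleles: tuple[str, ...]


def panel_summary(
    peptide_id: str,
    measurements: Iterable[AffinityMeasurement],
    panels: Optional[Mapping[str, AllelePanel]] = None,
    config: Optional[ScreenConfig] = None,
) -> dict[str, PanelSummary]:
    """Summarize one peptide's affinities over each allele panel.

    Panel alleles absent from the measurements are reported as missing,
    never imputed.  Censored values participate in counting (as none) but
    not in the best-affinity minimum.
    """
    cfg = config or ScreenConfig()
    panels = panels or cfg.panels
    rows = {m.allele: m for m in measurements if m.peptide_id == peptide_id}
    _check_duplicates(rows.values())
    out = {}
    for name, panel in panels.items():
        n_strong = n_weak = 0
        best: Optional[float] = None
        missing = []
        for allele in panel.alleles:
            m = rows.get(allele)
            if m is None:
                missing.append(allele)
                continue
            call = classify_affinity(m, cfg)
            if call.binder_class is BinderClass.strong:
                n_strong += 1
            elif call.binder_class is BinderClass.weak:
                n_weak += 1
            if not m.censored:
                ic50 = m.ic50_value_nM
                best = ic50 if best is None else min(best, ic50)
        best_tier = AffinityTier.none
        if best is not None:
            best_tier = classify_affinity(
                AffinityMeasurement(peptide_id, "best", panel.alleles[0].split("*")[0], ic50_nM=best),
                cfg,
            ).affinity_tier
        if missing:
            logger.warning("panel %s: missing alleles %s for %s", name, missing, peptide_id)
        out[name] = PanelSummary(panel, n_strong, n_weak, best, best_tier, tuple(missing))
    return out


AFFINITY_COLUMNS = ["peptide_id", "allele", "locus", "scale", "value", "censored"]


def read_affinity_tsv(path: str | Path) -> list[AffinityMeasurement]:
    """Read an affinity table (long format, one peptide x allele per row)."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(AFFINITY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"affinity TSV {path}: missing columns {sorted(missing)}")
    measurements = []
    for row in frame.itertuples(index=False):
        value = float(row.value)
        scale = str(row.scale)
        kwargs = dict(
            peptide_id=row.peptide_id,
            allele=row.allele,
            locus=row.locus,
            censored=bool(int(row.censored)),
            source=str(getattr(row, "source", "") or ""),
        )
        if scale == "pic50":
            if value < 0:
                logger.info(
                    "pIC50 %.3f for %s x %s read as positive (spurious leading minus)",
                    value, row.peptide_id, row.allele,
                )
                value = -value
            measurements.append(AffinityMeasurement(pic50=value, **kwargs))
        elif scale == "ic50_nM":
            measurements.append(AffinityMeasurement(ic50_nM=value, **kwargs))
        else:
            raise ValidationError(f"unknown affinity scale {scale!r}")
    return measurements


def calls_to_frame(
    measurements: Iterable[AffinityMeasurement], config: Optional[ScreenConfig] = None
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        call = classify_affinity(m, config)
        rows.append(
            {
                "peptide_id": m.peptide_id,
                "allele": m.allele,
                "locus": m.locus,
                "pic50": None if m.censored else m.pic50_value,
                "ic50_nM": m.ic50_value_nM,
                "censored": m.censored,
                "binder_class": call.binder_class.value,
                "affinity_tier": call.affinity_tier.value,
            }
        )
    return pd.DataFrame(rows)
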