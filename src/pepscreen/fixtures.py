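"""Packaged study tables and a seeded synthetic-data generator.

The packaged fixture set carries the published screening tables for the
seven bovine milk allergens: the 24 peptides surviving simulated
gastrointestinal digestion, the 7 peptides recovered after in vitro
digestion, the curated IgE/T-cell epitope catalog, per-locus binder
counts, the peptide x allele IC50 matrix (censored ">5000 nM" entries
included), cytokine-induction and bioactivity summaries, and the MS
identification summary.  Known printed inconsistencies in the sources are
carried as-is with an annotation flag rather than silently corrected.

The synthetic generator plants cleavage sites and binder classes with
known ground truth so that every pipeline stage can be checked for exact
recovery.  Planted proteins use a background alphabet inert to the default
enzyme set (no K/R, F/L/W/Y, M/H, P, C or D), so the only cleavage sites
are the planted lysines and recovery must be perfect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


import numpy as np
import pandas as pd

from .annot import (
    BioactivityTag,
    Cytokine,
    CytokineRecord,
    read_bioactivity_tsv,
    read_cytokine_tsv,
    summarize_scores,
)
from .binding import AffinityMeasurement, LocusCounts, read_affinity_tsv
from .digestion import digest
from .epitopes import EpitopeRecord, read_epitope_tsv
from .io import (
    PeptideFragment,
    ProteinRecord,
    Source,
    ValidationError,
    read_fasta,
    read_peptide_tsv,
    write_fasta,
    write_peptide_tsv,
)
from .msqc import MSIdentification, read_ms_tsv

_DATA_FILES = (
    "milk_proteins.fasta",
    "is_peptides.tsv",
    "iv_peptides.tsv",
    "epitopes.tsv",
    "binder_counts.tsv",
    "affinity_ic50.tsv",
    "cytokines.tsv",
    "bioactivity.tsv",
    "ms_identifications.tsv",
    "cleavage_rules.yaml",
)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pepscreen.data").joinpath(name)))


def _verify_checksums() -> None:
    manifest = json.loads(_data_path("checksums.json").read_text())
    for name in _DATA_FILES:
        digest_ = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if digest_ != manifest[name]:
            raise ValidationError(f"packaged data file {name} is corrupted (checksum mismatch)")


@dataclass
class PaperFixtureSet:
    """The published tables, typed and cross-linked."""

    proteins: dict[str, ProteinRecord]
    is_peptides: list[PeptideFragment]
    iv_peptides: list[PeptideFragment]
    epitopes: list[EpitopeRecord]
    binder_counts: dict[tuple[str, str], LocusCounts]  # (source, peptide_id) -> counts
    affinities: dict[str, list[AffinityMeasurement]]  # source -> measurements
    cytokines: list[CytokineRecord]
    bioactivity: list[BioactivityTag]
    ms_identifications: list[MSIdentification]

    def peptide(self, sequence: str) -> PeptideFragment:
        for p in self.is_peptides + self.iv_peptides:
            if p.sequence == sequence:
                return p
        raise KeyError(sequence)


def load_paper_fixtures(verify: bool = True) -> PaperFixtureSet:
    """Load and cross-link every packaged table."""
    if verify:
        _verify_checksums()
    proteins = {p.id: p for p in read_fasta(_data_path("milk_proteins.fasta"))}
    is_peptides = read_peptide_tsv(_data_path("is_peptides.tsv"))
    iv_peptides = read_peptide_tsv(_data_path("iv_peptides.tsv"))

    bc_frame = pd.read_csv(_data_path("binder_counts.tsv"), sep="\t")
    binder_counts = {
        (row.source, row.peptide_id): LocusCounts.from_row(row.peptide_id, row._asdict())
        for row in bc_frame.itertuples(index=False)
    }

    aff_all = read_affinity_tsv(_data_path("affinity_ic50.tsv"))
    affinities = {
        "IS": [m for m in aff_all if m.source == "IS"],
        "IV": [m for m in aff_all if m.source == "IV"],
    }
    fixtures = PaperFixtureSet(
        proteins=proteins,
        is_peptides=is_peptides,
        iv_peptides=iv_peptides,
        epitopes=read_epitope_tsv(_data_path("epitopes.tsv")),
        binder_counts=binder_counts,
        affinities=affinities,
        cytokines=read_cytokine_tsv(_data_path("cytokines.tsv")),
        bioactivity=read_bioactivity_tsv(_data_path("bioactivity.tsv")),
        ms_identifications=read_ms_tsv(_data_path("ms_identifications.tsv")),
    )
    _check_cross_references(fixtures)
    return fixtures


def _check_cross_references(fx: PaperFixtureSet) -> None:
    known = {p.sequence for p in fx.is_peptides} | {p.sequence for p in fx.iv_peptides}
    for source, pid in fx.binder_counts:
        if pid not in known:
            raise ValidationError(f"binder-count row for unknown peptide {pid!r}")
    for ms in fx.affinities.values():
        for m in ms:
            if m.peptide_id not in known:
                raise ValidationError(f"affinity row for unknown peptide {m.peptide_id!r}")
    for rec in fx.cytokines:
        if rec.peptide_id not in known:
            raise ValidationError(f"cytokine row for unknown peptide {rec.peptide_id!r}")
    for tag in fx.bioactivity:
        if tag.peptide_id not in known:
            raise ValidationError(f"bioactivity row for unknown peptide {tag.peptide_id!r}")


# --------------------------------------------------------------------------
# synthetic data

#: residues that trigger no clause of pepsin (either pH), trypsin or
#: chymotrypsin (either specificity) and take part in no blocking exception
INERT_ALPHABET = "ASTGEQNIV"

DEFAULT_ALLELES = (
    ("DRB1*01:01", "DRB1"), ("DQ7", "DQ"), ("DQ8", "DQ"),
    ("DRB1*03:01", "DRB1"), ("DRB1*14:19", "DRB1"), ("DRB1*14:21", "DRB1"),
)


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic bundle.

    Defaults mirror the screened milk-protein data: protein lengths around
    the 142-607 residue range of the seven allergen precursors, IC50 drawn
    log-uniformly over [1, 10000] nM (the span of the printed affinity
    matrix), SVM scores normal around the 0.2 induction threshold.
    """

    n_proteins: int = 7
    length_min: int = 140
    length_max: int = 610
    cleavage_site_density: float = 0.08  # per-bond planting probability
    n_strong_per_peptide: int = 5
    strong_ic50_range_nM: tuple[float, float] = (1.0, 100.0)
    nonbinder_ic50_range_nM: tuple[float, float] = (6000.0, 10000.0)
    svm_score_mean: float = 0.2
    svm_score_sd: float = 0.5
    min_peptide_length: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cleavage_site_density <= 1.0:
            raise ValidationError("cleavage_site_density must lie in [0, 1]")
        if self.length_min < 2 or self.length_max < self.length_min:
            raise ValidationError("invalid length range")


@dataclass
class SyntheticBundle:
    """Generated inputs plus the planted ground truth."""

    proteins: list[ProteinRecord]
    planted_cut_positions: dict[str, set[int]]
    peptides: list[PeptideFragment]
    affinities: list[AffinityMeasurement]
    planted_strong: dict[str, set[str]]  # peptide_id -> alleles planted strong
    cytokines: list[CytokineRecord]
    window_scores: dict[tuple[str, str], list[float]]  # (peptide, cytokine) -> scores


def generate_synthetic(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate a seeded, bit-reproducible synthetic screening bundle.

    Proteins are drawn over the inert background alphabet with lysines
    planted independently at each bond position with the requested density;
    the planted positions are exactly the cleavage sites of the default
    enzyme set.  Every digestion survivor receives an affinity row per
    allele (strong binders planted at known alleles) and per-cytokine
    window scores.
    """
    rng = np.random.default_rng(spec.seed)
    background = np.array(list(INERT_ALPHABET))
    proteins: list[ProteinRecord] = []
    planted_cuts: dict[str, set[int]] = {}
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        letters = rng.choice(background, size=length)
        plant = rng.random(length - 1) < spec.cleavage_site_density
        cut_sites = {int(b) + 1 for b in np.flatnonzero(plant)}
        for bond in cut_sites:
            letters[bond - 1] = "K"
        pid = f"SYN{i + 1:03d}"
        proteins.append(ProteinRecord(id=pid, name="synthetic protein", sequence="".join(letters)))
        planted_cuts[pid] = cut_sites

    peptides: list[PeptideFragment] = []
    for protein in proteins:
        result = digest(protein, min_length=spec.min_peptide_length)
        peptides.extend(result.survivors)

    affinities: list[AffinityMeasurement] = []
    planted_strong: dict[str, set[str]] = {}
    alleles = list(DEFAULT_ALLELES)
    seen: set[str] = set()
    for pep in peptides:
        if pep.sequence in seen:
            continue  # identical survivors share one affinity row set
        seen.add(pep.sequence)
        n_strong = min(spec.n_strong_per_peptide, len(alleles))
        strong_idx = set(rng.choice(len(alleles), size=n_strong, replace=False).tolist())
        planted_strong[pep.sequence] = {alleles[k][0] for k in strong_idx}
        for k, (allele, locus) in enumerate(alleles):
            lo, hi = (
                spec.strong_ic50_range_nM if k in strong_idx else spec.nonbinder_ic50_range_nM
            )
            ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            affinities.append(
                AffinityMeasurement(
                    peptide_id=pep.sequence, allele=allele, locus=locus,
                    ic50_nM=ic50, source="SYN",
                )
            )

    cytokines: list[CytokineRecord] = []
    window_scores: dict[tuple[str, str], list[float]] = {}
    for seq in sorted(seen):
        n_windows = max(0, len(seq) - 9 + 1)
        for cytokine in Cytokine:
            scores = rng.normal(spec.svm_score_mean, spec.svm_score_sd, size=n_windows)
            scores = [float(s) for s in scores]
            window_scores[(seq, cytokine.value)] = scores
            cytokines.append(summarize_scores(seq, cytokine, scores))
    return SyntheticBundle(
        proteins, planted_cuts, peptides, affinities, planted_strong, cytokines, window_scores
    )


def write_synthetic_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write a generated bundle as FASTA + TSV files plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteins, out / "proteins.fasta")
    write_peptide_tsv(bundle.peptides, out / "peptides.tsv")
    aff_rows = [
        {
            "peptide_id": m.peptide_id, "allele": m.allele, "locus": m.locus,
            "scale": "ic50_nM", "value": m.ic50_nM, "censored": 0, "source": m.source,
        }
        for m in bundle.affinities
    ]
    pd.DataFrame(aff_rows).to_csv(out / "affinity.tsv", sep="\t", index=False)
    cyt_rows = [
        {
            "peptide_id": r.peptide_id, "cytokine": r.cytokine.value,
            "n_inducing": r.n_inducing,
            "score_min": "" if r.score_min is None else r.score_min,
            "score_max": "" if r.score_max is None else r.score_max,
            "window_length": r.window_length,
        }
        for r in bundle.cytokines
    ]
    pd.DataFrame(cyt_rows).to_csv(out / "cytokines.tsv", sep="\t", index=False)
    truth = {
        "planted_cut_positions": {k: sorted(v) for k, v in bundle.planted_cut_positions.items()},
        "planted_strong_alleles": {k: sorted(v) for k, v in bundle.planted_strong.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
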