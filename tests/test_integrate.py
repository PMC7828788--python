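"""16-factor radar scoring tests, with a shoelace-formula oracle computing
polygon areas from explicit vertex coordinates."""

import math

import numpy as np
import pytest

from pepscreen import (
    BioactivityTag,
    BioFunction,
    CytokineRecord,
    Cytokine,
    Verdict,
    build_features,
    load_paper_fixtures,
    normalize,
    radar_area,
    score_vector,
    verdict,
)
from pepscreen.binding import panel_summary
from pepscreen.integrate import (
    ALLERGENIC_RANGE,
    FeatureVector16,
    N_FACTORS,
    SECTOR_ANGLE,
    TOLEROGENIC_RANGE,
)


def shoelace_total(r):
    """Independent oracle: shoelace formula on the explicit 16 vertices."""
    xs = [r[k] * math.cos(k * SECTOR_ANGLE) for k in range(N_FACTORS)]
    ys = [r[k] * math.sin(k * SECTOR_ANGLE) for k in range(N_FACTORS)]
    s = 0.0
    for k in range(N_FACTORS):
        j = (k + 1) % N_FACTORS
        s += xs[k] * ys[j] - xs[j] * ys[k]
    return abs(s) / 2.0


def shoelace_sector(r, i, j):
    """Oracle for a sector: sum of origin-anchored triangles i..j-1."""
    area = 0.0
    for k in range(i - 1, j - 1):
        xa, ya = r[k] * math.cos(k * SECTOR_ANGLE), r[k] * math.sin(k * SECTOR_ANGLE)
        xb, yb = (
            r[k + 1] * math.cos((k + 1) * SECTOR_ANGLE),
            r[k + 1] * math.sin((k + 1) * SECTOR_ANGLE),
        )
        area += abs(xa * yb - xb * ya) / 2.0
    return area


class TestRadarArea:
    def test_all_zeros(self):
        assert radar_area(np.zeros(16)) == 0.0

    def test_all_ones_closed_form(self):
        assert radar_area(np.ones(16)) == pytest.approx(8.0 * math.sin(math.pi / 8), abs=1e-12)

    def test_single_axis_has_zero_area(self):
        r = np.zeros(16)
        r[4] = 1.0
        assert radar_area(r) == 0.0
        assert radar_area(r, ALLERGENIC_RANGE) == 0.0

    def test_matches_shoelace_oracle(self, rng):
        for _ in range(500):
            r = np.array([rng.random() for _ in range(16)])
            assert radar_area(r) == pytest.approx(shoelace_total(r), abs=1e-9)
            assert radar_area(r, ALLERGENIC_RANGE) == pytest.approx(
                shoelace_sector(r, *ALLERGENIC_RANGE), abs=1e-9)
            assert radar_area(r, TOLEROGENIC_RANGE) == pytest.approx(
                shoelace_sector(r, *TOLEROGENIC_RANGE), abs=1e-9)

    def test_scale_equivariance(self, rng):
        r = np.array([rng.random() for _ in range(16)])
        for c in (0.25, 0.5, 2.0):
            assert radar_area(c * r) == pytest.approx(c * c * radar_area(r), rel=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(Exception):
            radar_area(np.ones(15))


class TestBuildFeatures:
    def test_no_evidence_is_all_zero(self):
        vec = build_features("pep")
        assert np.all(vec.raw == 0)

    def test_fixture_binder_counts_fill_factors_1_to_6(self, paper):
        counts = paper.binder_counts[("IS", "DTQAIVQNNDSTE")]
        vec = build_features("DTQAIVQNNDSTE", binder_counts=counts)
        assert list(vec.raw[:6]) == [7, 1, 5, 1, 4, 2]

    def test_cytokine_and_bioactivity_mapping(self):
        records = [CytokineRecord("pep", Cytokine.IL10, 2, 0.3, 0.9)]
        tags = [BioactivityTag("pep", BioFunction.anti_inflammatory, 1)]
        vec = build_features("pep", cytokine_records=records, tags=tags)
        assert vec.raw[12] == pytest.approx(0.9)  # factor 13: IL-10 score
        assert vec.raw[15] == 1.0                 # factor 16: anti-inflammatory

    def test_il10_database_tag_backfills_factor_13(self):
        tags = [BioactivityTag("pep", BioFunction.il10_inducer, 2)]
        vec = build_features("pep", tags=tags)
        assert vec.raw[12] == 1.0

    def test_noninducing_record_contributes_zero(self):
        records = [CytokineRecord("pep", Cytokine.IL4, 0, None, None)]
        vec = build_features("pep", cytokine_records=records)
        assert vec.raw[8] == 0.0


class TestNormalize:
    def test_panel_max_uses_locus_sizes(self):
        raw = np.zeros(16)
        raw[3] = 6  # DRB1-strong out of 12 alleles
        vec = FeatureVector16("pep", raw)
        normalize([vec], "panel-max")
        assert vec.normalized[3] == pytest.approx(0.5)

    def test_batch_max_fixed_point(self):
        raws = [np.zeros(16), np.zeros(16)]
        raws[0][8], raws[1][8] = 2.0, 1.0
        vectors = [FeatureVector16(f"p{i}", r) for i, r in enumerate(raws)]
        normalize(vectors, "batch-max")
        assert vectors[0].normalized[8] == 1.0
        assert vectors[1].normalized[8] == pytest.approx(0.5)

    def test_all_zero_column_stays_zero(self):
        vectors = [FeatureVector16("p", np.zeros(16))]
        for scheme in ("panel-max", "batch-max"):
            normalize(vectors, scheme)
            assert np.all(vectors[0].normalized == 0)

    def test_negative_scores_floored_at_zero(self):
        raw = np.zeros(16)
        raw[8] = -0.4
        vec = FeatureVector16("pep", raw)
        normalize([vec], "panel-max")
        assert vec.normalized[8] == 0.0

    def test_normalized_range(self, paper):
        vectors = _paper_vectors(paper, "IS") + _paper_vectors(paper, "IV")
        for scheme in ("panel-max", "batch-max"):
            normalize(vectors, scheme)
            for vec in vectors:
                assert np.all(vec.normalized >= 0) and np.all(vec.normalized <= 1)


def _paper_vectors(paper, source):
    cytokines = [r for r in paper.cytokines if r.source == source]
    tags = [t for t in paper.bioactivity if t.source == source]
    peptides = paper.is_peptides if source == "IS" else paper.iv_peptides
    vectors = []
    for pep in peptides:
        counts = paper.binder_counts[(source, pep.sequence)]
        measured = {m.peptide_id for m in paper.affinities[source]}
        panels = (
            panel_summary(pep.sequence, paper.affinities[source])
            if pep.sequence in measured else None
        )
        vectors.append(build_features(pep, counts, panels, cytokines, tags))
    return vectors


class TestVerdict:
    def test_clear_dominance(self):
        assert verdict(0.5, 0.1) is Verdict.allergenic_dominant
        assert verdict(0.1, 0.5) is Verdict.tolerogenic_dominant

    def test_inert_when_both_below_floor(self):
        assert verdict(0.0, 0.0) is Verdict.inert

    def test_dual_within_margin(self):
        assert verdict(0.30, 0.29) is Verdict.dual

    def test_ssnicniscdk_scores_allergenic_dominant(self, paper):
        """Soft qualitative check: the Bos d 4 peptide that binds four DQ
        alleles strongly and strongly induces IL-4 should come out
        allergenic-dominant under the default scheme."""
        vectors = _paper_vectors(paper, "IS")
        normalize(vectors)
        by_id = {v.peptide_id: v for v in vectors}
        score = score_vector(by_id["SSNICNISCDK"])
        assert score.verdict is Verdict.allergenic_dominant
        assert score.allergenic_area > score.tolerogenic_area
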