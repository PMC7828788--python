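# pepscreen

Integrated *in silico* screening of food-protein peptides for allergenic
versus tolerogenic potential, built around the cow's-milk allergens
(α-lactalbumin, β-lactoglobulin, serum albumin and the four caseins).

Dietary proteins are broken down by digestive proteases; fragments of nine
or more residues can sit in the MHC class II binding groove, be presented to
helper T cells, and — depending on the alleles engaged and the cytokines
induced — drive either sensitization (IgE class switching via IL-4) or
tolerance (IL-10, protective HLA alleles, anti-inflammatory activity).
`pepscreen` chains the *in silico* counterparts of that path:

1. **Digestion** — rule-based cleavage-site prediction (Keil P4…P4′ window
   rules transcribed from the ExPASy PeptideCutter documentation) for pepsin
   (pH 1.3 and pH > 2), trypsin, and chymotrypsin (high- and low-specificity),
   with simultaneous multi-enzyme digestion and a ≥ 9-residue survivor filter.
2. **Epitope mapping** — interval matching of surviving peptides against a
   curated IgE / T-cell epitope catalog, and comparison of peptide sets
   (e.g. simulated digest vs LC-MS-identified *in vitro* digest).
3. **MHC II binding classification** — strong binder when pIC50 > 6.3,
   weak when 5.3 < pIC50 ≤ 6.3 (pIC50 = 9 − log₁₀ IC50[nM]); IC50 tiers
   high < 50 nM, intermediate < 500 nM, low < 5000 nM; per-locus binder
   counts over 12 HLA-DRB1, 5 HLA-DQ and 7 HLA-DP alleles; summaries over a
   milk-allergy susceptibility panel (DRB1\*01:01, DQ7, DQ8) and a protection
   panel (DRB1\*03:01, DRB1\*14:19, DRB1\*14:21).
4. **Immuno-annotation** — ingestion of IL-4 / IFNγ / IL-10 induction
   predictor summaries (SVM scores, inducing-window counts at threshold 0.2)
   and bioactivity tags (immunomodulatory, antimicrobial, anti-inflammatory).
5. **Integrated score** — a 16-factor radar polygon on axes at equal angles
   2π/16, factors normalized to [0, 1]; the pro-allergenic sector spans
   factors 4–9 and the tolerogenic sector factors 10–16, each sector scored
   as its fan of origin-anchored triangles,
   area = ½·sin(2π/16)·Σ rₖ·rₖ₊₁, and the two areas compared into a verdict
   (allergenic-dominant / tolerogenic-dominant / dual / inert).
6. **MS QC** — Mascot-score filtering (cut-off 32) of identification
   summaries and replicate homogeneity via Manhattan distances on the
   (score, emPAI) plane.

The package bundles the published screening tables as fixtures (peptides,
epitopes, binder counts, the IC50 matrix, cytokine/bioactivity summaries, MS
identifications) together with the seven precursor sequences, so the full
pipeline runs offline; a synthetic-data generator plants cleavage sites and
binder classes with known ground truth for exact-recovery testing.

## Worked example

```python
import pepscreen as ps
from pepscreen.binding import panel_summary
from pepscreen.integrate import build_features, normalize, score_vector

fx = ps.load_paper_fixtures()

# digest bovine alpha-lactalbumin (precursor numbering, signal peptide included)
for s in ps.digest(fx.proteins["P00711"]).survivors:
    print(s.sequence, f"{s.start}-{s.end}", ps.is_fixed_point(s.sequence))
```

```
DTQAIVQNNDSTE 56-68 True
SSNICNISCDK 88-98 True
```

Two fragments of the 142-residue precursor survive pepsin + trypsin +
chymotrypsin digestion at nine or more residues, and neither contains an
internal cleavage site (each is a digestion fixed point).

```python
cyt  = [r for r in fx.cytokines if r.source == "IS"]
tags = [t for t in fx.bioactivity if t.source == "IS"]
vectors = []
for pep in fx.is_peptides:
    counts = fx.binder_counts[("IS", pep.sequence)]
    measured = {m.peptide_id for m in fx.affinities["IS"]}
    panels = (panel_summary(pep.sequence, fx.affinities["IS"])
              if pep.sequence in measured else None)
    vectors.append(build_features(pep, counts, panels, cyt, tags))
normalize(vectors)          # panel-max scheme
for v in vectors:
    if v.peptide_id == "SSNICNISCDK":
        s = score_vector(v)
        print(s.allergenic_area, s.tolerogenic_area, s.verdict.value)
```

```
0.0919 0.0000 allergenic_dominant
```

SSNICNISCDK binds only DQ alleles (four of them strongly) and is a strong
IL-4 inducer but carries no tolerogenic evidence, so its pro-allergenic
sector area (0.092) dwarfs its tolerogenic area (0) and the peptide is
flagged allergenic-dominant — a candidate to prioritize for serum IgE
verification.

The same stages are available from the shell:

```bash
pepscreen digest --fasta proteins.fasta --out peptides.tsv
pepscreen compare --set-a is_peptides.tsv --set-b iv_peptides.tsv
pepscreen score --peptides peptides.tsv --affinities affinity.tsv --out scores.tsv
pepscreen fixtures --synthetic --out syn/   # seeded bundle with ground truth
```

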