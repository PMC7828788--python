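# Methods

## Scope and model

`pepscreen` screens food-protein peptides for allergenic versus tolerogenic
potential by chaining deterministic, rule-based stages: simulated
gastrointestinal digestion, epitope interval mapping, MHC class II
binding-strength classification, aggregation of external cytokine/bioactivity
predictions, and a 16-factor radar-polygon score. No stage is statistical:
the package recomputes nothing that upstream machine-learning predictors
(binding-affinity, cytokine-induction or allergenicity models) produce — their
outputs are ingested as tables and treated as opaque evidence.

Coordinates are 1-based and inclusive on the precursor sequence (signal
peptide included), matching how peptide positions are conventionally quoted
for these allergens.

## Digestion engine

Protease specificity is expressed in the Keil window nomenclature: the bond
between P1 and P1′ is examined with up to four residues of context on each
side (P4…P1 N-terminal, P1′…P4′ C-terminal). A rule is a set of positive
clauses plus a set of exception clauses; each clause constrains window slots
with an allowed-set or a forbidden-set, and a bond is cut iff at least one
positive clause holds and no exception clause does. Exception clauses exist
because trypsin's blocking patterns (CKD, DKD, CKH, CKY, CRK, RRH, RRR)
cannot be written as a disjunction of positive clauses. The shipped tables
(`data/cleavage_rules.yaml`) transcribe the ExPASy PeptideCutter
documentation for trypsin, both chymotrypsin specificities, and both pepsin
variants; they are data, not code, so corrections need no code change.

**Terminus semantics.** A clause fails when any slot it constrains falls
outside the sequence: no phantom residues are invented either to satisfy an
allowed-set or to escape a forbidden-set. This matches the regular-expression
implementation of the same tables (full lookbehind/lookahead windows) and is
required for re-digestion idempotence: a surviving fragment, examined in
isolation, must not gain cleavage sites at its ends (e.g. PFPGPIPNSL, whose
final S|L bond is protected in the parent by a proline at P2′ that lies
outside the fragment; waiving out-of-range forbidden constraints would cut
it).

**Multi-enzyme digestion** takes the union of single-enzyme cut sets on the
intact precursor — simultaneous exposure, not sequential rounds — and
fragments are the maximal uncut runs, which tile the parent exactly.
Survivors are fragments of ≥ 9 residues (inclusive: a 9-mer survives),
the minimum length the MHC class II groove accepts.

**Default enzyme set: pepsin (pH > 2), trypsin, chymotrypsin
low-specificity.** The choice is calibrated on the seven bovine milk
allergen precursors: this set, and no other combination of the shipped
variants, reproduces the 24 published surviving peptides exactly (sequences
and spans; 2/1/5/4/3/5/4 per protein). The discriminating observations are:
Y/W at P1′ must be pepsin-cleavable (ruling out the pH 1.3 variant, whose
hydrophobic set is {F, L}), and M|E, M|A and H|V bonds must cut (ruling out
chymotrypsin high-specificity, whose P1 set is {F, Y, W}). Both pepsin and
both chymotrypsin variants remain selectable.

Kinetics, partial digestion and missed cleavages are out of scope: the model
is a binary site predictor, which overstates degradation relative to in vivo
digestion (discussed below under limitations).

## Binding classification

pIC50 and IC50 interconvert exactly via pIC50 = 9 − log₁₀(IC50 in nM).
Binder classes use the proteochemometric convention: strong iff
pIC50 > 6.3, weak iff 5.3 < pIC50 ≤ 6.3. Affinity tiers use the IEDB
convention with half-open bins, upper bound excluded: high < 50 nM,
intermediate < 500 nM, low < 5000 nM; ≥ 5000 nM and censored "> 5000"
entries are non-binders. The two scales are mutually consistent except in
(500, 501.19) nM: 10^(9−6.3) = 501.19 nM, so the conventional "strong means
IC50 < 500 nM" shorthand is a rounding of the pIC50 rule. The pIC50 rule is
authoritative when both scales are supplied.

Per-locus counts run over the 24-allele prediction panel (12 HLA-DRB1,
5 HLA-DQ, 7 HLA-DP); each allele contributes to exactly one class, so
strong + weak + none equals the number of measured alleles. Allele-panel
summaries (susceptibility: DRB1\*01:01, DQ7, DQ8; protection: DRB1\*03:01,
DRB1\*14:19, DRB1\*14:21) report strong/weak counts and the minimum IC50;
missing panel alleles are reported, never imputed.

## Epitope mapping and set comparison

Epitope matches are quantified (overlap length, overlap fraction of the
peptide, interval-relation class: exact / peptide-within-epitope /
epitope-within-peptide / partial) and never thresholded — the literature uses
both strict and loose senses of "matches", so verdicts are left to the
report layer. Peptide-set comparison classifies each cross pair with
precedence identical (equal sequence strings) > containment (strict
substring) > overlapping (coordinate overlap on the same parent without a
substring relation); the categories are therefore mutually exclusive per
pair and symmetric between the two sets.

## Cytokine and bioactivity evidence

An inducing window is one whose SVM decision score strictly exceeds the
threshold (default 0.2, the predictors' published default; window lengths 9
or 15). Summaries store the inducing count and the score range over inducing
windows only. A consistency checker flags records reporting more inducing
windows than the peptide has (the bundled published table contains several
such rows — e.g. 7 IL-4 inducers for a 14-mer with six 9-mer windows, 4 for
an 11-mer with three — whose counting unit upstream is unknowable from the
summary); flags are reports, not errors, because curated fixtures must load
as printed.

## The 16-factor integrated score

Factor order is fixed and part of the public contract (permuting factors
within a sector changes its area): 1–3 weak binder counts per locus
(DRB1, DQ, DP), 4–6 strong binder counts per locus, 7–8 strong/weak counts
in the susceptibility panel, 9 IL-4 score, 10 IFNγ score, 11–12 strong/weak
counts in the protection panel, 13 IL-10 score, 14–16 binary
immunomodulatory / antimicrobial / anti-inflammatory evidence. Cytokine
factors carry the maximum inducing-window score (0 if nothing induces); an
IL-10 database tag backfills factor 13 with 1.0 when no scored record
exists.

Two normalization schemes ship because "normalized to one" admits both
readings; both guarantee values in [0, 1]:

* **panel-max** (default): count factors divided by their theoretical maxima
  (locus sizes 12/5/7; panel size 3); score factors floored at 0 and divided
  by the batch maximum; binary factors pass through. Comparable across
  batches for the count factors.
* **batch-max**: every factor divided by its batch maximum (all-zero columns
  stay zero). Fully data-driven, not comparable across batches.

With axes at equal angles θ = 2π/16, the polygon area is the fan
½·sin θ·Σ rₖ·rₖ₊₁ — cyclic for the total, an open chain of origin-anchored
triangles for a contiguous sector. The pro-allergenic sector spans factors
4–9 and the tolerogenic sector 10–16; factors 1–3 enter only the total,
since weak binding across loci can matter in both reaction types. IFNγ is
kept in the tolerogenic sector by the adopted order although its
pro-inflammatory reading is equally defensible; interpret factor 10 in both
contexts. Consequences worth knowing: a single nonzero axis has zero area
(isolated evidence never dominates), scaling all factors by c scales every
area by c², and the total is bounded by the all-ones polygon,
8·sin(π/8) ≈ 3.0615.

The verdict compares sector areas with a relative margin (default 0.1) and
an inertness floor (default 0.01): allergenic-dominant, tolerogenic-dominant,
dual (comparable and both above floor), or inert. No published area values
exist to calibrate against; the defaults are chosen so that clear one-sided
evidence dominates and near-ties read as dual. The qualitative behaviour is
validated against the published narrative (the DQ-restricted strong binder
and strong IL-4 inducer SSNICNISCDK scores allergenic-dominant under the
default scheme).

## MS identification QC

The Mascot score filter is inclusive (score ≥ cut-off retained; default 32,
the significance threshold computed for the bundled search). Replicate
homogeneity uses Manhattan distance on the (score, emPAI) plane per
identification key, over every replicate pair, for keys present in all
replicates (absent keys are excluded and listed). Because score and emPAI
live on incomparable scales, each dimension is divided by its pooled
standard deviation by default; a raw mode is retained since the source
procedure does not state whether it standardized. Keys whose minimum
pairwise distance exceeds a flag level (default: the mean pairwise distance)
are reported heterogeneous.

## Packaged data

`data/milk_proteins.fasta` carries the seven precursor sequences (UniProt
P00711, P02754, P02769, P02662, P02663, P02666, P02668) as a transcription
bundled for offline use; it is verified in the test suite against 59
independent published constraints (protein lengths, survivor spans, epitope
sequences with coordinates), and `scripts/fetch_uniprot.py` retrieves the
authoritative entries when a network is available. The screening tables are
carried as printed, including their internal inconsistencies
(length-vs-span mismatches on two peptides, inducing-window overcounts),
which are flagged by the validators rather than corrected. A checksum
manifest guards the packaged files against silent corruption.

## Synthetic data

The generator emulates the study's structure, not milk-protein biology:
proteins of 140–610 residues (the span of the seven precursors) drawn from a
background alphabet inert to every shipped protease rule
(A, S, T, G, E, Q, N, I, V — no P1 triggers, no prolines, no residues that
participate in blocking exceptions), with lysines planted independently per
bond at density 0.08 so the planted positions are exactly the cleavage
sites of the default enzyme set. Affinities are planted per surviving
peptide: 5 strong alleles at IC50 log-uniform over [1, 100] nM and
non-binders over [6000, 10000] nM (unambiguously outside the weak band), so
classification must recover the planted classes exactly; IC50 values across
the published matrix span [0.53, > 5000] nM, which the log-uniform choice
reflects. SVM window scores are normal with mean 0.2 (the induction
threshold) and SD 0.5, giving roughly half-inducing windows. Seeded runs
are bit-reproducible.

What passing synthetic tests do **not** show: real proteases act on real
compositional biases (prolines, disulfide-constrained regions), real
affinities cluster near class boundaries, and real predictor scores are
correlated across overlapping windows. The synthetic bundle proves the
plumbing and the threshold logic exact, not the biology.

## Numerical choices and degenerate inputs

* Conversion round-trip pIC50 → IC50 → pIC50 holds to 1e−12 relative
  tolerance; classification at float-noise distance of a class boundary
  follows the computed value.
* Radar areas agree with a shoelace evaluation of the explicit vertices to
  1e−9 absolute.
* Empty measurement sets yield zero counts; empty score lists yield
  n_inducing = 0 with no range; a window longer than the peptide yields no
  windows (not an error); single-peptide batches under batch-max leave
  all-zero columns at zero.
* Validation of peptide fragments reports inconsistencies (interval
  ordering, length vs span, substring identity against the parent) and never
  mutates or rejects — printed tables must load as printed.

## Known limitations

* Binary cleavage rules overstate digestion: no kinetics, no missed
  cleavages, no matrix/emulsion protection, no inter-individual enzyme
  variability. Fragment sets are best read as a lower bound on surviving
  length-≥ 9 peptides.
* Upstream predictor quality bounds everything downstream; the package
  propagates, but cannot audit, their errors.
* The radar score is a screening heuristic: factor weights are implicit in
  the normalization denominators and the fixed factor order, and no area
  threshold has clinical meaning. Verdicts rank candidates for wet-lab
  verification; they are not allergenicity claims.
* The two normalization schemes can disagree on borderline verdicts; the
  score TSV carries both raw and normalized factors so any scheme can be
  re-derived.
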