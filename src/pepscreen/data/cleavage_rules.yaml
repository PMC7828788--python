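# Protease specificity tables in Keil P4..P4' nomenclature, transcribed from
# the ExPASy PeptideCutter documentation.
#
# Semantics: the bond between the residues at P1 and P1' is cut iff at least
# one entry under `clauses` is satisfied and no entry under `exceptions` is
# satisfied.  Each clause maps a window slot (P4, P3, P2, P1, P1', P2', P3',
# P4') to either `allowed: <residues>` (the slot must hold one of these) or
# `forbidden: <residues>` (the slot must not hold any of these).  A clause
# fails when one of its constrained slots falls outside the sequence: no
# phantom residues are invented to satisfy (or escape) a constraint.
version: 1
enzymes:
  trypsin:
    clauses:
      - {P1: {allowed: KR}, "P1'": {forbidden: P}}
      - {P2: {allowed: W}, P1: {allowed: K}, "P1'": {allowed: P}}
      - {P2: {allowed: M}, P1: {allowed: R}, "P1'": {allowed: P}}
    exceptions:
      - {P2: {allowed: CD}, P1: {allowed: K}, "P1'": {allowed: D}}
      - {P2: {allowed: C}, P1: {allowed: K}, "P1'": {allowed: HY}}
      - {P2: {allowed: C}, P1: {allowed: R}, "P1'": {allowed: K}}
      - {P2: {allowed: R}, P1: {allowed: R}, "P1'": {allowed: HR}}
  chymotrypsin_high:
    clauses:
      - {P1: {allowed: FY}, "P1'": {forbidden: P}}
      - {P1: {allowed: W}, "P1'": {forbidden: MP}}
    exceptions: []
  chymotrypsin_low:
    clauses:
      - {P1: {allowed: FLY}, "P1'": {forbidden: P}}
      - {P1: {allowed: W}, "P1'": {forbidden: MP}}
      - {P1: {allowed: M}, "P1'": {forbidden: PY}}
      - {P1: {allowed: H}, "P1'": {forbidden: DMPW}}
    exceptions: []
  pepsin_ph1.3:
    clauses:
      - {P3: {forbidden: HKR}, P2: {forbidden: P}, P1: {forbidden: R},
         "P1'": {allowed: FL}, "P2'": {forbidden: P}}
      - {P3: {forbidden: HKR}, P2: {forbidden: P}, P1: {allowed: FL},
         "P2'": {forbidden: P}}
    exceptions: []
  pepsin_ph2:
    clauses:
      - {P3: {forbidden: HKR}, P2: {forbidden: P}, P1: {forbidden: R},
         "P1'": {allowed: FLWY}, "P2'": {forbidden: P}}
      - {P3: {forbidden: HKR}, P2: {forbidden: P}, P1: {allowed: FLWY},
         "P2'": {forbidden: P}}
    exceptions: []
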