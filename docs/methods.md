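# Methods

This note documents the models, rules and numerical choices behind
`nc1var`, what the synthetic data generator does and does not emulate,
and the known limitations.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Domain definition

The NC1 domain is defined sequence-intrinsically: it begins at the first
residue after the final Gly-X-Y triplet of the collagenous domain and
runs to the protein's C-terminus.  The detector scans from the
C-terminus for the last position `i` carrying Gly at `i`, `i-3` and
`i-6` — three in-frame repeats.  Requiring three (rather than two)
in-frame Gly is deliberate: NC1 domains contain incidental Gly pairs
spaced three apart (in the α5 chain, Gly1510/Gly1513), and a two-repeat
detector would place the boundary inside the domain.  Genuine
collagenous domains end in long uninterrupted repeat runs, so the
stronger condition costs nothing there.  Residue numbering is carried as
an explicit offset field (kidney isoform 2 coordinates for the α5
chain, e.g. Cys1482); nothing in the code assumes a particular offset.

## Variant enumeration and splice filtering

Each codon admits exactly nine single-nucleotide substitutions; their
consequences are called by codon translation (standard table only), and
missense changes are deduplicated to unique (residue, ref, alt) triples
with the producing SNVs retained — downstream statistics are computed at
whichever granularity a question needs (nucleotide-level for the rate
model, amino-acid-level for cohort counts).  Flanking CDS bases are
recorded per SNV as the context for the rate model; a domain must
therefore not abut the very ends of the CDS (in practice the collagenous
region precedes it and the stop codon follows).

The splice exclusion rule: a variant within 3 bases of an annotated
splice site is excluded when `mut ≤ 0.85 × wt` with strictly positive
`wt`.  A non-positive wild-type score makes a percentage drop undefined;
such variants are flagged indeterminate rather than silently excluded.
Exon boundaries come from a sidecar TSV in CDS coordinates, keeping the
CDS type free of exon structure.  The built-in scorer is a log-odds
position-weight-matrix over packaged donor (9-mer) and acceptor (23-mer)
base-frequency tables reflecting the canonical human consensus; it is a
default, not a contribution — the scorer interface accepts any callable,
or precomputed wild-type/mutant score pairs.  An amino-acid substitution
is dropped only when *every* producing SNV is splice-excluded.

## Structural environments

SASA is Shrake–Rupley (biotite implementation) with a 1.4 Å probe and
single-atom van der Waals radii; relative accessibility divides by the
residue type's theoretical maximum.  A residue is *buried* at RSA < 0.09.
Disulphides are Cys pairs with SG–SG ≤ 2.5 Å, matched greedily by
distance so each Cys joins at most one bond.  Salt bridges pair opposite
formal charges (Asp/Glu vs Lys/Arg; His is treated as neutral) with
charged-group heavy atoms within 5.0 Å; side-chain hydrogen bonds use a
3.5 Å donor–acceptor cutoff over side-chain N/O atoms.  Backbone φ/ψ are
computed only across intact peptide bonds (C–N ≤ 2.5 Å); chain breaks
leave them undefined.  Secondary structure is a coarse assignment from
φ/ψ basins (helix, strand) plus a CA-trace bend criterion (≥ 70°
deviation over i−2…i+2, only where the backbone is covalently
continuous); a precomputed assignment may be supplied instead.  Residues
missing backbone atoms or Cβ are flagged "no structural data" and are
excluded from every downstream numerator and denominator; a strict mode
additionally requires the full heavy-atom side chain.

## Damage classification

Fifteen catalogue features; "cis Pro replaced" is deliberately absent
because the α5 NC1 domain contains no cis prolines.  The rules are
deterministic functions of (substitution, environment, thresholds):

- disulphide breakage: reference is a disulphide-bonded Cys;
- buried Gly replaced / buried Pro introduced / buried charge
  introduced, replaced, switched / buried hydrophilic introduced:
  burial plus the respective identity or class transition
  (hydrophobic = AVLIMFWC, hydrophilic = RNDQEKHSTY);
- buried salt-bridge breakage: buried charged reference in a bridge,
  substitute cannot carry the same charge;
- buried H-bond breakage: buried reference with a recorded side-chain
  H-bond, substitute side chain lacking N/O donor/acceptor capacity;
- buried/exposed switch: hydrophobicity-class inversion within ±0.05 RSA
  of the burial threshold (a proxy — the original formulation uses the
  mutant model's RSA, which a substitution-only pipeline does not have);
- clash: side-chain volume gain exceeding the estimated free local
  volume, `40 + 400 × RSA` Å³ (volume proxies from mean residue
  volumes; buried sites tolerate ~40 Å³, exposed sites effectively
  cannot clash);
- cavity altered: |volume change| ≥ 70 Å³ at a buried site;
- disallowed φ/ψ: Gly reference at φ > 0 (Gly-only territory);
- Gly in a bend; secondary structure altered (Pro into helix/strand).

These are geometric proxies of the published feature definitions, not a
reimplementation of any external tool; where exact agreement with an
external classifier matters, its per-variant output is ingested via
`load_external_classifications` and flows through the identical
downstream machinery.  All thresholds live in `ClassifierConfig`.

## Substitution-rate null model

The expected proportion of variants triggering feature c is the
rate-weighted fraction e_c = Σ_{v triggers c} r(v) / Σ_v r(v) over all
candidate missense SNVs with structural data (splice-excluded variants
and no-structure residues are removed from numerator and denominator
alike).  The default rate table r(left, ref→alt, right) has 192 entries:
transitions 4× transversions, CpG transitions (C→T before G, G→A after
C) a further 10× — the qualitative shape of human germline mutation
spectra.  The exact published parameterisation of the neighbour-dependent
model used for the curated expected percentages is not recoverable, so
those percentages are consumed as fixture inputs wherever published
inferences are reproduced; the default table is used for synthetic
pipelines.  Expected proportions are scale-invariant in the rates.

Observed counts are tested with the exact binomial test (scipy
`binomtest`; no normal approximation), one-sided ("greater") by default
for enrichment claims with two-sided available — the packaged checks all
hold under either convention.  Feature-level significance uses α/15
(0.0033 at α = 0.05) regardless of how many features have nonzero
counts; any-damage uses α.

## Conservation

A residue is conserved when its alignment column carries the identical
amino acid in all six chains; a gap anywhere makes the column
non-conserved.  The alignment is consumed from file (aligned FASTA or
Clustal); no aligner is embedded.  Damage–conservation association is
Fisher's exact test (two-sided by default) on the conserved × damaging
table over all possible substitutions with structural data, repeatable
with Cys variants excluded; the null spectrum can be recomputed over
conserved residues only.

## Family-level survival

The family is the unit of analysis, included once: affected males only;
mosaic males and males with additional COL4A3–COL4A5 pathogenic variants
are dropped first; families left with no males are excluded with a
machine-readable reason.  If any remaining male reached kidney failure
the family contributes an event at the mean of the available ages (a
reported range enters at its midpoint; a pre-aggregated family median is
used when it is the only age information, and never overrides individual
ages).  Otherwise the family is censored at the latest review age.
Kaplan–Meier fitting and the log-rank test come from lifelines; the
median is the earliest time survival reaches 0.5 (undefined medians are
reported as not reached).  The IQR is computed from the event times of
families with events — with heavy censoring the curve-based quartiles
are frequently undefined, so this convention is used and stated, without
claiming it matches any external convention.

Classifier evaluation against curated labels scores sensitivity over
P/LP variants and specificity over B/LB; VUS and conflicting labels are
excluded.

## Synthetic data

`generate_domain` plants the hallmark composition of an α5 NC1 domain at
the real landmark coordinates: 231 residues numbered 1457–1687, 12 Cys
(1482…1687) paired into 6 disulphides, 4 buried Gly (1492, 1510, 1602,
1624), 13 exposed Gly, 105 fully conserved alignment columns always
including the Cys and buried Gly.  The protein is embedded after a
Gly-X-Y stretch so the domain detector, back-translated to a CDS
deterministically under the seed, and realised as a three-layer lattice
slab (4.6 Å spacing): disulphide pairs occupy separated middle-layer
edges with SG atoms at bonding distance, designated buried residues sit
in the middle layer's interior, exposed Gly on the face rims.  The slab
shape is what keeps the buried fraction near the ~20–25% typical of a
globular domain — a compact ball of 231 residues would bury roughly
half.  Only burial, bonding and distances are physically meaningful; the
backbone is discontinuous, so φ/ψ- and secondary-structure-dependent
features are exercised through directly constructed environments in the
tests, not through the synthetic structure.  Consequently, passing tests
demonstrate the rule machinery and the statistics, not the geometry of
any real fold.

Cohorts are sampled without replacement with odds multiplied by
`damaging_enrichment` for damaging substitutions: 3.0 yields a
pathogenic-database-like cohort (~50% damaging against the generator's
~25% base), 0.4 a population-like cohort (~12%); labels correlate with
damage status with 5% noise.  Clinical cohorts draw Weibull event ages
(shape 4.0, scale set by the target median of 31 years) with independent
uniform review-age censoring calibrated to the requested fraction;
occasional age ranges, multi-male families, female-only families and
mosaic individuals exercise every aggregation rule.  The shape parameter
is chosen so that the family-level median is estimable to ±2 years at
the design size of 200 families — a spread (SD ≈ 9 years) somewhat
narrower than published NC1 interquartile ranges suggest, which is the
price of that estimability.

All generators are deterministic under their seed, byte-for-byte.

## Curated tables

The published database surveys (Cys substitutions, Gly substitutions,
observed-vs-expected damage counts, kidney-failure summaries) ship as
TSV fixtures with pinned SHA-256 checksums.  The flattened source from
which the Cys table was transcribed interleaves its database columns;
the assignment packaged here is the unique one consistent with every
stated marginal (29 LOVD substitutions in 49 families; 21 ClinVar
substitutions over 10 of 12 residues, 16 shared with LOVD; a single
gnomAD variant).  These tables are inputs: the package reproduces the
statistical inferences drawn from them, while the counts themselves
depend on database contents and an external classifier and are not
recomputed.

The real NM_033380.3 coding sequence is not redistributed; a fixture
slot under `data/reference/` accepts a user-supplied copy, enabling the
real-transcript enumeration (231-codon domain, 1,345 unique missense
substitutions) and its acceptance check.

## Problem sizes

The test suite and acceptance script run the full pipeline at the
domain's natural size (231 codons, 2,079 SNVs, ~1,380 substitutions) and
the calibration properties at their stated designs (100 seeds × 200
families for median recovery; 400 label permutations for log-rank
calibration; 40 seeds for cohort-enrichment recovery); the whole suite
completes in well under a minute on one CPU.

## Known limitations

- The damage rules are substitution-side proxies; no mutant side-chain
  repacking or rotamer modelling is performed, and features defined on
  the mutant model (buried/exposed switch in particular) are
  approximated as documented above.
- The default rate table is parametric (ts/tv 4, CpG 10), not estimated
  from genome data.
- The synthetic structure validates rule logic, not fold realism; a real
  structure (e.g. the published α5 NC1 crystal structure) should be used
  for real-variant classification, via `StructureModel.from_pdb`.
- Hexamer-interface effects, ligand-binding sites and cross-link
  chemistry are out of scope.
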