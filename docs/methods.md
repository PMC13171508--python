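# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic data generator does and does not emulate, and the
numerical details a user would need to reproduce or extend the analysis.

## Activity curation

IC50 values are stored in nanomolar; an optional units column (pM/nM/µM/mM/M)
is converted on ingest. pIC50 = 9 − log₁₀(IC50 nM). Rows are removed, with
this precedence, when the IC50 is missing/non-numeric/non-positive, when the
SMILES fails to parse, or when the canonical SMILES duplicates an earlier
row. Deduplication keeps the first occurrence and does not aggregate
discordant replicate IC50s (a warning is logged); no salt stripping or
standardization beyond RDKit canonicalization is applied. The curation
report satisfies the accounting identity n_input = n_retained + Σ removals
by construction.

Class boundaries are half-open: pIC50 ≥ 8 is active, pIC50 < 6 inactive,
the rest intermediate. The published class ranges elsewhere in the source
tables suggest a 5/6 boundary may have been used for some analyses; the
stated ≥8 / <6 rule is adopted and both cut-offs are exposed in
`ActivityThresholds` so either convention can be reproduced.

## Descriptors

The eight descriptors are RDKit's average molecular weight, Crippen
atom-contribution LogP, Lipinski donor/acceptor counts, rotatable-bond
count, Ertl TPSA, heteroatom count and aromatic-ring count. The Crippen
estimate is used wherever a LogP-like quantity appears, including the
"ALogP" slot of MPO scoring; commercial ALogP implementations differ by a
few tenths, so cross-tool comparisons should be directional. Acceptor
counts are convention-dependent across toolkits (Lipinski counts every N/O);
donor counts and TPSA are stable and are what the exact tests pin down.
Tables are rendered at full precision; published-value comparisons round to
one decimal.

## EDA

Moments are population moments (bias=True): skewness g₁ = m₃/m₂^1.5 and
excess kurtosis g₂ = m₄/m₂² − 3, which are the conventions consistent with
negative kurtosis entries for short-tailed descriptor distributions.
Samples with n < 3 or zero spread report both as undefined rather than
fabricating values.

The Mann–Whitney U test reports U for the first sample with midrank tie
handling. The exact null distribution is used when n₁·n₂ ≤ 400 and the
pooled sample is tie-free; otherwise the normal approximation with
tie-corrected variance and continuity correction. Degenerate inputs (all
values identical) report U = n₁n₂/2, p = 1 with a flag. Tests are
two-sided at α = 0.05 with all three pairwise class comparisons; no
multiplicity correction is applied by default.

PCA standardizes each descriptor to zero mean and unit population variance
(descriptors span orders of magnitude, so correlation-matrix PCA is the
only defensible scaling), drops zero-variance columns with a warning,
orders components by decreasing eigenvalue, and fixes signs so the
largest-magnitude loading in each component is positive — making loadings
reproducible across linear-algebra backends. Explained variance is
normalized to the full standardized variance, so it sums to 100% when all
components are kept.

## Scaffolds

Murcko scaffolds come from RDKit's implementation (ring systems plus
linkers; exocyclic multiply-bonded atoms retained). Acyclic molecules have
an empty scaffold and are reported in a separate bucket, never as a group.
Extraction is idempotent — the scaffold of a scaffold is itself — and this
is enforced by tests at scale.

In the diversity summary, Ncsk counts ring-containing *molecules*, not
distinct skeletons: the published tallies have Ncsk (210) far above Ns (69)
within one class, which is only arithmetically consistent with a
per-molecule count, and the printed ratios confirm it. Scaffold groups are
sorted by descending member count with canonical-SMILES tie-breaks; the
scaffold class applies the molecule-level thresholds to the group's mean
pIC50. Functional-group profiling matches a documented SMARTS set
(aromatic [a], amide C(=O)N, hydroxyl [OX2H], ether [OD2]([#6])[#6], amine
[NX3;!$(NC=O)], carbonyl [CX3]=[OX1], ring nitrogen [#7;R], halogen
[F,Cl,Br,I]); users can override the set, and invalid patterns fail naming
the offending entry. Printed SMILES from typeset tables often contain
typographic spaces; every reader strips whitespace before parsing.

## QSAR

Fingerprints are folded binary Morgan fingerprints, radius 2, 2048 bits by
default (the standard QSAR featurization; both parameters configurable).
All ten regressors share one random 80:20 split (seed 42 by default, no
stratification) and one 5-fold shuffled KFold on the training partition, so
cross-validation never sees the held-out rows — the uncontaminated choice
when the protocol is otherwise unstated. Tree learners run single-threaded
with fixed seeds, making reports bit-reproducible. Linear penalized models
use α = 0.01 (lasso/elastic net): with sparse binary features and a target
spanning ~2 log units, the textbook α = 1 shrinks every coefficient to
zero and the models would degenerate to intercepts. Ridge keeps α = 1.

Grid-search tuning targets the boosted-tree model, scoring candidates by
mean training-partition CV R²; the default grid is n_estimators
{100, 300, 500} × max_depth {3, 5, 7} × learning_rate {0.01, 0.05, 0.1} ×
subsample {0.8, 1.0}. The pipeline's orchestrated run uses a reduced
2×2×2 grid, which on the synthetic series selects settings within CV noise
of the full grid at a fraction of the cost. R² is the coefficient of
determination; RMSE is in pIC50 units.

## Desirability and enumeration

Each property's desirability is trapezoidal on transitions x1<x2<x3<x4:
0 below x1, linear up to 1 at x2, plateau to x3, linear down to 0 at x4;
ties x1=x2 or x3=x4 give step edges. The default profile (MW 300/350/520/
580 Da, ALogP 1/2/4/5, PSA 60/80/130/150 Å², HBA 4/5/9/11, HBD 0/1/2/3,
with very-high importance on MW/ALogP/PSA and high on HBA/HBD; importance →
weight map 1.0/0.75/0.5/0.25) encodes oral drug-likeness for this series.
Note the HBD curve deliberately scores HBD = 0 as 0 — a donor-free molecule
is treated as undesirable, as profiled.

The aggregate is the weight-normalized **geometric** mean of the five
desirabilities. The choice is deliberate: starting scaffolds in this series
score near zero on published MPO scales precisely because a single
disqualifying property (ALogP > 5, or PSA < 60 Å²) should sink the
aggregate, and an arithmetic mean cannot reproduce that annihilation — it
floors such scaffolds near 0.3–0.4. A weighted arithmetic mean remains
available (`aggregation="arithmetic"`) for profiles where compensation
between properties is wanted. Published MPO values from commercial tools
use an unpublished curve shape and are treated as ordinal, not numeric,
references.

Enumeration takes scaffolds with `[*:n]`-labelled attachment points and
fragments with exactly one wildcard; fragments join by a single bond
(RDKit molzip), H is the null substituent, and no ring fusion is attempted.
Products are deduplicated by canonical SMILES (symmetric sites collapse),
scored, sorted by descending MPO with SMILES tie-breaks, given dense ranks,
and truncated at the cap after ranking. Every analogue necessarily contains
the parent core as a substructure.

## Synthetic data generator

The generator emulates a curated single-target ChEMBL activity table: five
cores — the four high-potency nitrogen-heterocycle scaffolds of the series
and benzene as the low-potency counterweight — each with two para
attachment sites, decorated from a 14-fragment substituent library (plus
H). True potency is additive on the log scale: scaffold base (8.9, 9.2,
9.1, 8.8 for the heterocycles; 6.0 for benzene) plus per-substituent
effects in [−0.30, +0.40] plus Gaussian noise (σ = 0.5 pIC50 by default).
Per-scaffold counts (60/55/55/50/90) total 310 molecules; with the default
noise the realized class split lands within a few molecules of
211/56/43 — the bases were chosen by normal-tail arithmetic to hit those
proportions, since additive effects with sd ≈ 0.3 plus σ = 0.5 noise give a
total spread of ≈ 0.6 around each base. Duplicate rows (3%) and
missing-IC50 rows (3%, drawn from unused analogues so they are never also
duplicates) are appended after the shuffled unique block, so first-
occurrence deduplication provably removes exactly the injected rows.
Everything is driven by one `numpy` Generator seed; identical specs give
byte-identical CSV/JSON output.

Because effects are additive per occupied site and each
(scaffold, site, fragment) junction lights up its own fingerprint bits,
noise-free potency is exactly linear in the binary fingerprint — which is
why ridge regression attains R² ≈ 1 at σ = 0 and why tree ensembles
cross-validate near 0.8 at σ = 0.5. What the generator does **not**
emulate: assay heterogeneity and unit chaos of real ChEMBL extracts,
activity cliffs, stereochemistry-dependent potency, scaffold counts in the
dozens (it uses 5 cores, not 124), or acyclic actives. Tests passing on
this data therefore validate the machinery — accounting, recovery,
learnability, null behaviour — not any claim about real HMGR SAR.

The recovery check asserts that pipeline-extracted Murcko scaffolds match
the ledger cores for ≥ 99% of molecules (in practice 100%: all fragments
are acyclic, so decoration never changes the core), that the distinct-
scaffold count matches the ledger exactly, and optionally that tree-
ensemble CV R² ≥ 0.5 under default noise.

## Orchestration and problem sizes

The pipeline runs curate → descriptors → eda → scaffolds → qsar → design,
writing plain CSV/JSON (and SVG depictions) plus a manifest with the
package version, a hash of the result-determining configuration, the seed
and per-stage row counts. Re-running an identical configuration reproduces
stage outputs byte for byte; any stage failure aborts with the stage name,
retaining partial outputs.

Default problem sizes — 310 molecules, 2048-bit fingerprints, ten models,
the reduced 8-point tuning grid, and a 1000-molecule scaffold-idempotence
sweep — were chosen so the full synthetic study completes in about a minute
on a single core while still exercising every stage at realistic scale.

## Known limitations

- Structure-based stages (docking, growth-vector geometry, binding-energy
  estimation, synthetic-accessibility scoring, molecular dynamics) are out
  of scope; the design stage is purely ligand-based.
- Exact-with-ties Mann-Whitney enumeration is not implemented; tied samples
  always use the corrected normal approximation.
- MPO scores depend on the descriptor conventions (Crippen LogP, Lipinski
  acceptors); absolute values are not comparable across toolkits, only
  orderings.
- The duplicate rule keeps the first occurrence; replicate-aggregation
  strategies (median/geometric mean of IC50s) are not provided.
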