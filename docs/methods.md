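# Methods

`chemprofile` quantifies the chemical diversity and complexity of molecule
libraries the way comparative database studies in food chemistry and drug
discovery do: standardize every structure, profile physicochemical
properties and molecular complexity, decompose the library into
Bemis–Murcko scaffolds, classify polyphenols by a structural rule, condense
four diversity criteria into a Consensus Diversity Plot, and draw the
occupied chemical space with a satellite-based projection. This note
records the models, the defaults and the numerical choices, and what the
synthetic test data does and does not establish.

## Curation

Raw records (SMILES lines or SDF entries) are standardized by an open,
fully specified rule set:

1. **Largest fragment.** Multi-fragment inputs keep the organic
   (carbon-containing) fragment with the most heavy atoms; counterions are
   never preferred over an organic fragment regardless of size. Remaining
   ties break by molecular weight, then by lexicographically smallest
   canonical SMILES, so the choice is deterministic.
2. **Neutralization.** Protonation states are neutralized where a neutral
   form exists (carboxylates to acids, ammoniums to amines, phenolates to
   phenols, via RDKit's Uncharger). Permanently charged species such as
   quaternary ammonium stay charged.
3. **Canonicalization.** Output is RDKit canonical isomeric SMILES;
   stereochemistry survives standardization because the stereocenter count
   downstream needs it.

The composite map is idempotent (verified property), and within a library
duplicates — identical canonical SMILES — collapse to the first occurrence.
Stereoisomers with identical constitution are distinct by default;
`stereo_distinct=False` merges them. Proprietary "wash" implementations
make different micro-decisions, so curated counts from this module are
comparable *within* analyses run with it, not bit-for-bit with closed
tools. A `CurationLog` keeps the arithmetic honest:
`n_output = n_input − n_duplicates_removed − n_unparseable`.

Library overlap is plain intersection of canonical-SMILES sets and is
refused when two libraries were curated under different settings.

## Physicochemical and complexity profiling

Six properties per molecule, by their standard published definitions as
implemented in RDKit: SlogP (Crippen additive logP), TPSA (Ertl, Å²), AMW
(average molecular weight, g/mol), RB (rotatable bonds), HBD and HBA.
For the donor/acceptor counts we use the Lipinski conventions — NH/OH
count for HBD, N+O count for HBA — the most common choice for
cross-database comparison panels; swapping in RDKit's pharmacophore-based
acceptor count would change HBA systematically, which is why the convention
is fixed and recorded here.

Complexity is Fsp3 (fraction of sp³ carbons among all carbons; reported as
missing, not 0, for carbon-free molecules) and the number of tetrahedral
stereocenters *including unassigned potential centers* — database entries
frequently omit stereo annotations, and counting potential centers is what
makes complexity comparable across sources that annotate inconsistently.

Library summaries report mean, sample SD (n−1), type-7 (linear
interpolation) quartiles and a boxplot whisker rule placed at
**median ± 1.5·IQR**, counting the points outside as omitted outliers.
That median-centered rule is deliberately the default (it is the rule the
comparative analyses this package mirrors actually apply); the conventional
Tukey rule (q1/q3 ± 1.5·IQR) is available via `outlier_rule="tukey"`.

## Scaffolds and the recovery curve

The scaffold of a molecule is its Bemis–Murcko core: the union of ring
systems and the linkers connecting them, all side chains removed. RDKit's
Murcko implementation is used, which keeps exocyclic double-bonded atoms
attached to the core (cyclohexanone's scaffold retains its carbonyl) —
standard behavior, stated here because conventions differ. Ring-free
molecules fall into a reserved `ACYCLIC` pseudo-scaffold that is a
first-class frequency category by default (acyclic content is a headline
number for natural-product-like collections); `include_acyclic=False`
covers the other convention.

Scaffold diversity is the area under the scaffold recovery curve: order
scaffolds by descending count (ties lexicographic, for deterministic
curves), plot cumulative fraction of molecules (y) against cumulative
fraction of distinct scaffolds (x) from (0,0) to (1,1), integrate by
trapezoids. AUC lives in [0.5, 1]: 0.5 means every scaffold equally
populated (maximally scaffold-diverse), values near 1 mean a few scaffolds
dominate.

Two structural facts about this statistic shaped the test design and are
worth knowing when interpreting it:

- A table with a single scaffold has AUC exactly 0.5 — the curve is the
  diagonal — even though a one-scaffold library is intuitively the least
  diverse. The statistic is only informative for tables with ≥ 2 categories.
- Because x is the *fraction* of distinct scaffolds, adding many rare
  scaffolds to a table with a fixed dominant block *raises* the AUC (the
  dominant block's x-width shrinks). AUC therefore decreases with scaffold
  count only under near-uniform assignment. The ordering checks in the test
  suite consequently generate libraries with uniform scaffold quotas
  (`scaffold_skew=0`) and a small (2%) acyclic block; under those
  conditions mean AUC over seeds is strictly decreasing in scaffold count
  (≈0.74 / 0.54 / 0.51 for 1 / 10 / 100 scaffolds at n=500).

Reference-scaffold matching canonicalizes the reference structures with the
same scaffold extractor before intersecting, and summarizes a numeric
annotation column (mean, sample SD) over the matched rows.

## Polyphenol rule

A molecule is polyphenolic when it has **≥ 2 phenolic hydroxyls** (an OH
bonded directly to an aromatic carbon; SMARTS `[OX2H1][c]` — ethers and
esters excluded) **or one biphenol motif** (two directly bonded, non-fused
aromatic rings each bearing ≥ 1 such hydroxyl). Two readings of the rule
are genuinely open and both are implemented:

- The default counts both hydroxyls even on one ring, so catechol
  qualifies; `distinct_rings=True` requires hydroxyls on two different
  aromatic rings.
- Heteroaromatic rings bearing OH on an aromatic carbon count as phenolic
  (the rule speaks of aryl rings generally).

Phenolates neutralize to phenols during curation, so deprotonated inputs
classify correctly. The rule is monotone: adding an aromatic hydroxyl can
never turn a polyphenol into a non-polyphenol (property-tested).

## Global diversity and the Consensus Diversity Plot

Each library is condensed to four numbers:

- **median_tanimoto** — median Tanimoto similarity of 166-bit MACCS
  structural keys over molecule pairs (x-axis; lower = more diverse).
  MACCS dialects differ between toolkits; the dialect (RDKit public keys)
  is recorded in output metadata. Two all-zero fingerprints compare as 1.0
  by documented convention. Above `max_pairs` (default 10⁶) pairs the
  median is estimated on a seeded uniform pair sample; the estimator stays
  within 0.02 of the exhaustive median at n=200 (acceptance-tested over
  25 seeds).
- **scaffold_auc** — recovery-curve AUC as above (y-axis; lower = more
  diverse).
- **pcp_distance** — mean intra-library pairwise Euclidean distance of the
  six properties after auto-scaling (z-scores) with mean/SD pooled over
  *all* libraries under comparison (point color). Pooling is what makes the
  statistic invariant to affine changes of units applied uniformly across
  libraries, and what makes values comparable between libraries in one
  plot. Properties constant across the pool are dropped with a warning.
- **size** — library size (point area).

The aggregation choices the underlying plot methodology leaves open —
scaling population and per-library aggregate — are fixed to pooled scaling
and mean pairwise distance, the simplest defensible reading, and both are
function parameters. Quadrants are assigned against thresholds that default
to the per-axis medians across the compared libraries; a profile exactly on
a threshold goes to the lower/left (more diverse) side, a documented
tie-break so assignments are deterministic.

## Satellite-based chemical-space projection

Rather than embedding an n×n similarity matrix, each molecule is described
by its Tanimoto similarity to k satellite molecules; the n×k matrix is
column-centered and reduced by SVD to 2–3 principal directions. The model
(satellites, column means, loadings, explained-variance fractions) is
serializable, so new libraries can be projected into a frozen map — the
operation that makes database-vs-database maps cheap (n·k similarities
instead of n²).

- Satellites: default `min(200, n)` chosen by greedy farthest-point
  (MaxMin) selection under 1−Tanimoto from a seeded start; a seeded uniform
  random mode exists. MaxMin spreads satellites over the occupied space,
  which is the premise of the satellite idea; the count and rule are
  recorded in the model.
- With k = n the construction reduces *exactly* to classical principal
  component scores of the full centered similarity matrix
  (acceptance-tested to 1e−8 against an independent PCA).
- Axis signs are fixed by making the largest-magnitude loading of each
  component positive, so plots are reproducible across runs and platforms.
- Map quality is monitored by the Spearman correlation between embedded
  Euclidean distances and full-fingerprint 1−Tanimoto distances over a
  seeded pair sample; it is reported as missing for zero-variance
  embeddings.

## Synthetic libraries

The generator emulates the statistical structure of multi-source chemical
databases, not their chemistry. A scaffold pool is enumerated from six ring
templates (benzene, cyclohexane, tetrahydropyran, cyclohexene, pyridine,
furan) joined pairwise/triply by short alkyl linkers; every pool member is
verified to be its own Murcko scaffold. Molecules are assigned to scaffolds
by a normalized power law over scaffold ranks (exponent `scaffold_skew`,
0 = uniform) using deterministic largest-remainder quotas, then decorated
with 0–3 substituents from a fixed drug-like vocabulary (methyl, ethyl,
propyl, hydroxyl, methoxy, chloro, fluoro, carboxyl). Polyphenol records
receive ≥ 2 hydroxyls on aromatic carbons; non-polyphenol records never
receive an aromatic hydroxyl, so generation flags and the structural
classifier agree by construction (checked, with disagreements counted, in
the tests). Acyclic records are random branched alkane/ether/alcohol trees
of 3–9 heavy atoms. Curation noise: a fraction of records is emitted as
sodium salts of their acids or with a NaCl contaminant fragment, and a
fraction is re-emitted as atom-order permutations of earlier records
(exercising canonicalization-based deduplication, not string equality).

Defaults mirror a large food-chemical collection: 32% acyclic, 13.5%
polyphenols, `scaffold_skew=1.0`, 5% salt noise, 5% duplicates. The
generator is deterministic: same spec and seed give byte-identical records
and truth table.

What passing tests on this data does **not** show: real databases have far
larger scaffold vocabularies, correlated property distributions,
tautomer/stereo annotation inconsistencies and genuinely ambiguous salt
forms. Synthetic results validate the *machinery* (contracts, invariants,
estimator accuracy, determinism), not any empirical claim about a specific
database.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale problems chosen to
exercise every code path: libraries of 22–500 molecules, 1–100 scaffolds,
10–25 seeds per stochastic check. Pair statistics switch to sampling above
`max_pairs` pairs; tests use 10⁴–2×10⁴ sampled pairs. Tolerances: AUC vs
brute force 1e−12 (pure arithmetic), projection vs PCA 1e−8 (SVD
round-off), affine invariance 1e−10, sampled-vs-exhaustive median 0.02
(estimator design target). Degenerate inputs have defined behavior rather
than errors where a convention exists (all-zero fingerprints → similarity
1.0; carbon-free Fsp3 → missing; zero-variance embedding → flat map with a
warning; constant pooled property → dropped with a warning).

## Known limitations

- No tautomer canonicalization; tautomers count as distinct structures.
- The polyphenol rule is structural only; it does not distinguish
  flavonoids from non-flavonoids.
- The satellite count/selection defaults are heuristics; the quality metric
  (Spearman distance preservation) is the intended way to judge a map, not
  the defaults themselves.
- Curated counts are comparable only across runs of this standardizer, not
  with proprietary washing tools.
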