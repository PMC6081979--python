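# chemprofile

Chemoinformatic profiling of molecule libraries: how diverse, how complex,
and how do collections compare? The package implements the standard
comparative-analysis pipeline used for food-chemical, natural-product and
drug databases — curation, physicochemical profiling, Bemis–Murcko
scaffold analysis, polyphenol classification, Consensus Diversity Plots
and satellite-based chemical-space maps — as a reusable, tested library
with a CLI, plus a synthetic-library generator so everything runs without
downloading any proprietary database.

It is written for cheminformaticians and food-informatics researchers who
need reproducible answers to questions like: *what fraction of this
collection is acyclic or polyphenolic, which scaffolds dominate, and is
library A globally more diverse than library B?*

## The statistics at the core

For a curated library of N molecules:

- **Scaffold recovery AUC.** Bemis–Murcko scaffolds (ring systems plus
  linkers, side chains removed; ring-free molecules pooled as `ACYCLIC`)
  are ranked by descending frequency; the curve through
  (i/S, Σⱼ≤ᵢ cⱼ / N) from (0,0) to (1,1) is integrated by trapezoids.
  AUC ∈ [0.5, 1]; 0.5 ⇔ all scaffold counts equal (most diverse), → 1 when
  few scaffolds dominate.
- **Median fingerprint similarity.** Median Tanimoto coefficient
  T(a,b) = |a∧b| / |a∨b| of 166-bit MACCS keys over molecule pairs
  (seeded pair subsampling above 10⁶ pairs). Lower median = more
  structurally diverse.
- **Property diversity.** Mean intra-library pairwise Euclidean distance of
  six auto-scaled properties (SlogP, TPSA, AMW, RB, HBD, HBA), z-scored
  with mean/SD pooled over all libraries being compared.
- **Consensus Diversity Plot.** One point per library: median Tanimoto (x),
  scaffold AUC (y), property diversity (color), library size (area) —
  the most diverse libraries fall toward the lower left.
- **Polyphenol rule.** A molecule is polyphenolic iff it has ≥ 2 phenolic
  hydroxyls (OH on an aromatic carbon) or one biphenol motif (two directly
  bonded aromatic rings, each hydroxylated).
- **Complexity.** Fsp3 = (# sp³ carbons)/(# carbons) and the count of
  tetrahedral stereocenters including unassigned potential centers.
- **Satellite projection.** Each molecule is represented by its Tanimoto
  similarities to k reference "satellites"; the centered n×k matrix is
  reduced to 2–3 principal components. With k = n this equals classical
  PCA of the similarity matrix; with k ≪ n it scales to large libraries
  and lets new collections be projected into a fixed map.

See `docs/methods.md` for conventions, defaults and numerical choices.

## Worked example

```python
import chemprofile as cp
from chemprofile.scaffolds import recovery_curve, scaffold_frequencies

spec = cp.LibrarySpec(n_molecules=200, n_scaffolds=20, seed=11)
raw = cp.generate_library(spec)          # synthetic multi-source-style library
lib = cp.curate(raw.records, "demo")     # strip salts, neutralize, deduplicate
print(f"curated: {len(lib)} of {lib.log.n_input} "
      f"({lib.log.n_duplicates_removed} duplicates removed)")

freq = scaffold_frequencies(lib)
print(freq.top_k(3).to_string(index=False))
print(f"scaffold recovery AUC: {recovery_curve(freq).auc:.3f}")

n, frac, _ = cp.polyphenol_fraction(lib)
print(f"polyphenols: {n} ({100*frac:.1f}%)")
print(f"median MACCS Tanimoto: {cp.median_pairwise_tanimoto(lib, seed=0):.3f}")
```

Output:

```
curated: 190 of 200 (10 duplicates removed)
                        scaffold  count   percent
                         ACYCLIC     64 33.684211
     c1coc(CCc2ccccc2C2CCCCC2)c1     36 18.947368
C1=C(CCC2CCCCC2CCCc2cccnc2)CCCC1     18  9.473684
scaffold recovery AUC: 0.810
polyphenols: 27 (14.2%)
median MACCS Tanimoto: 0.322
```

Reading it: of 200 raw records, 10 were atom-order duplicates collapsed by
canonicalization. A third of the library is acyclic (the generator's
default emulates food-chemical collections), the top cyclic scaffold holds
~19% of molecules, and the recovery AUC of 0.81 says scaffold mass is
concentrated — a scaffold-redundant library. 14% of molecules carry at
least two aromatic hydroxyls, and the median pairwise MACCS similarity of
0.32 indicates broad structural spread.

The same analysis runs end-to-end from a config:

```bash
chemprofile generate --n 200 --seed 11 --out demo.smi
chemprofile run --config config.yaml     # curation → ... → CDP + chemical-space map
```

producing per-library CSV tables, the CDP (`cdp.svg`), chemical-space
coordinates/plots and a JSON manifest echoing every parameter and seed.

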