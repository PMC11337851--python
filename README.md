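# lrdmeta

Community-level analysis of paired metatranscriptomic and 16S rRNA gene
sequencing from perturbation experiments — built around the microcosm
design used to study deep-sea microbial responses to crude oil and
chemical dispersant (treatments BC, DISP, WAF, CEWAF, CEWAFN sampled at
days 0, 7, 17, 28 and 42).

It is aimed at microbial ecologists who have taxon-by-sample count
tables from both an RNA (expression) and a DNA (standing stock) assay
and want to ask: *which taxa are disproportionately active, and do the
treatments restructure the active community?*

## What it computes

**Taxonomy-threshold merging.** Raw taxonomic calls are canonicalized
against a local reference (synonyms, case/whitespace variants, homonyms)
and low-abundance calls are merged into higher ranks until every
retained label reaches a minimum relative-abundance resolution *T*
(default 4%). Per-sample totals are conserved exactly and the final
label set is rank-exclusive.

**The LRD activity index.** For taxon *i* in treatment *j*,

```
LRD_ij = (1/n) Σ_t log2( r_ijt / d_ijt )
```

with *r* and *d* the relative abundances in the metatranscriptomic and
16S libraries at timepoint *t*. Taxa are classified into activity
groups: Group I (mean LRD > 3.5, high synthetic capacity), Group II
(|mean LRD| ≤ 3.5), Group III (mean LRD < −3.5).

**Beta-diversity and ordination.** Bray-Curtis dissimilarity with
principal-coordinates analysis (classical metric scaling, negative
eigenvalues reported and excluded), plus analytic (hypergeometric)
rarefaction of species richness.

**Phylogenetic beta-diversity.** Abundance-weighted MPD (`comdist`)
and MNTD (`comdistnt`) between samples over a patristic distance
matrix from a newick reference tree.

**PERMANOVA.** Permutational multivariate ANOVA with sequential
(Type I) sums of squares for the factorial model

```
U = O + D + O×D + O×D×N + t + O×t + D×t + O×D×t + O×D×N×t
```

(O oil, D dispersant, N nutrients, t categorical time; 999 free
permutations by default), with honest handling of aliased terms and
saturated designs.

**Synthetic data.** A Dirichlet-multinomial generator reproduces the
microcosm layout (triplicate 16S, one RNA library per treatment ×
timepoint, CEWAFN present only at t0/t1/t4) with planted taxon
enrichments, so the full pipeline runs and is testable without any
sequencing archive.

## Worked example

```python
import pandas as pd
from lrdmeta import (CountTable, SimConfig, simulate_experiment,
                     taxonomy_reference, merge_to_threshold, compute_lrd)

cfg = SimConfig(seed=42, depth_rna=10_000, depth_dna=10_000)
rna, dna, designs, truth = simulate_experiment(cfg)

ref = taxonomy_reference(cfg)
joint = CountTable(pd.concat([rna.df, dna.df], axis=1))
merged, report = merge_to_threshold(joint, ref)   # 16 raw -> 15 labels

res = compute_lrd(CountTable(merged.df[rna.sample_ids]),
                  CountTable(merged.df[dna.sample_ids]), designs)
print(res.table.query("taxon in ('Colwellia','Bermanella','Amphritea','Methylophaga')"))
```

Selected rows of the output:

```
       taxon treatment  lrd_mean  n_used group
   Colwellia      DISP -0.001088       5    II
  Bermanella       WAF  4.016379       5     I
   Amphritea     CEWAF -4.829456       5   III
Methylophaga     CEWAF  3.919683       5     I
```

The simulator plants a 2⁴ RNA enrichment for *Bermanella* in WAF and
*Methylophaga* in CEWAF and a 2⁻⁴ depletion for *Amphritea* in CEWAF;
the estimated mean LRD recovers those log2 ratios (≈ +4 / −4) and
places the taxa in Groups I and III. *Colwellia*'s planted response is
an abundance bloom, not an RNA:DNA imbalance, so its LRD stays near 0
(Group II) while the bloom shows up instead in the Bray-Curtis
PERMANOVA as a dominant dispersant term.

The same analysis end-to-end, from the shell:

```sh
lrdmeta run --config config.yaml            # all artifacts + manifest.json
lrdmeta simulate --out sim/ --seed 7        # just the synthetic inputs
lrdmeta merge --table sim/dna.tsv --ref sim/taxonomy.tsv --out merged.tsv
lrdmeta betadiv --table merged.tsv --metric mntd --tree sim/tree.nwk --out mntd.tsv
lrdmeta permanova --dist mntd.tsv --design sim/design.tsv --permutations 999 --seed 1 --out report.tsv
```

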