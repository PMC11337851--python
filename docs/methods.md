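# Methods

## Scope and data model

The package analyses paired taxon-by-sample count tables: a
metatranscriptomic table (one library per treatment × timepoint cell)
and a 16S rRNA gene / OTU table (triplicate libraries per cell), tied
together by a sample design with binary factors O (oil/WAF), D
(dispersant), N (inorganic nutrients) and an ordinal timepoint t with
day values {0, 7, 17, 28, 42}. The five treatments are fixed functions
of the factors: BC = (0,0,0), DISP = (0,1,0), WAF = (1,0,0), CEWAF =
(1,1,0), CEWAFN = (1,1,1), with CEWAFN observed only at t0, t1 and t4.
All analyses start from annotated counts; read QC, assembly, annotation
and tree inference are upstream of this package.

## Taxonomy-threshold merging

Raw labels are resolved against a local reference table (label →
canonical, rank, parent) case- and whitespace-insensitively; synonyms
share a canonical entry, and homonyms are resolved toward the table's
majority domain (by total counts over unambiguous labels) or fall to the
configured unknown policy (`error`, or `bucket` into a reserved
`Unclassified` child of the root).

A label is *retained* at a node if the relative abundance of that node's
subtree (the summed abundance of all table rows whose lineage passes
through it) meets the threshold T under the retention rule —
`any_sample` (≥ T in at least one sample, the default) or `per_sample`
(≥ T in every sample). Rows are promoted one rank per pass, deepest
ranks first, until every assignment is retained or reaches the root
bucket; a final antichain closure reassigns each row to the shallowest
retained node on its lineage, so no output label is a strict descendant
of another and all samples share one label set. The root bucket is
exempt from the closure: it collects only rows whose entire lineage
failed retention, and coexists with the retained labels rather than
swallowing them. Aggregation sums the original counts, so per-sample
totals are conserved exactly (integer-exact for integer input), the
merge is idempotent, and raising T can only shrink the label set.

Default T = 0.04: the minimum relative-abundance resolution used in the
microcosm analysis this package re-implements. Normalization runs over
all rows present in the input table (no prior removal of unassigned
reads).

## The LRD index

LRD_ij = (1/n) Σ_t log2(r_ijt / d_ijt), where r and d are per-cell
relative abundances after replicate averaging (arithmetic mean of the
replicates' relative abundances, which keeps columns summing to 1) and n
is the number of admissible timepoints *for that treatment* — CEWAFN
contributes three, the others five. Zero handling is explicit because
log ratios are undefined at 0:

* `drop` (default): timepoints with r = 0 or d = 0 contribute nothing
  and n shrinks; rows with no admissible timepoint are omitted and
  listed in a skipped-rows report. No mass is invented.
* `pseudocount`: half the smallest nonzero relative abundance of the
  respective table is added everywhere before forming ratios. Useful
  when wholly RNA-silent taxa (candidate Group III members) must still
  receive a score.

Groups: I if mean LRD > 3.5, III if < −3.5, II otherwise (the boundary
±3.5 itself is Group II). The index is invariant to rescaling raw
counts (only proportions enter) and antisymmetric under exchanging the
RNA and DNA tables. LRD is intended to run on the merged (T = 4%) label
space; the pipeline driver enforces that by merging the two tables
jointly.

Because the index is built on relative abundances, it inherits
compositional closure: a strong planted enrichment of one taxon in a
cell deflates every other taxon's RNA fraction there, shifting their
ratios by −log2 of the complement's rescaling factor. This is a
property of the statistic on relative data, not a simulator artifact.

## Beta-diversity and ordination

Bray-Curtis: BC(A,B) = Σ|a_i − b_i| / Σ(a_i + b_i) (scipy's
implementation), defined on any nonnegative columns and invariant to
taxa absent from both samples; a pair of all-zero samples is an error.

PCoA is Gower's classical metric scaling: eigendecomposition of
−½ J D² J. Axes are ordered by descending eigenvalue; negative
eigenvalues (semi-metric inputs such as Bray-Curtis) are reported but
their axes excluded from the coordinates, and no Cailliez/Lingoes
correction is applied by default — transparency over silent adjustment.
Proportions explained are taken over the positive-eigenvalue total. For
Euclidean-embeddable input the coordinates reproduce the distances to
numerical precision (tested at 1e-6, observed ~1e-12).

Rarefaction is the analytic hypergeometric expectation
E[S] = Σ_i [1 − C(N−N_i, m)/C(N, m)] evaluated with log-gamma
arithmetic; a seeded Monte-Carlo subsampling mode exists for
comparison. The analytic form is used by default for determinism.

## Phylogenetic beta-diversity

The patristic matrix holds leaf-to-leaf sums of branch lengths from a
newick tree (every edge must carry a length; none are guessed).
Between samples A and B, with p the within-sample relative abundances
renormalized over tree-covered taxa:

* MPD(A,B) = Σ_i Σ_j p_iA p_jB pat(i,j) — the abundance-weighted mean
  pairwise distance;
* MNTD(A,B) = ½ [Σ_i p_iA min_{j∈B} pat(i,j) + Σ_j p_jB min_{i∈A}
  pat(i,j)] — the symmetric average of the two directional
  nearest-neighbor terms (the directions could also be reported
  separately; averaging is the package's contract and a flag away).

Conspecific taxa shared by both samples contribute zero nearest
distance by default; an `exclude_conspecifics` flag removes the
self-match (a taxon with no non-self neighbor then contributes 0).
Self-comparisons are evaluated by the same formulas — MPD(A,A) is the
within-sample diversity and may be positive — and the PERMANOVA ignores
the diagonal by construction (Gower centering uses only squared
off-diagonal distances symmetrically). MNTD ≤ MPD always.

## PERMANOVA

Gower's inner-product matrix G = −½ J D² J gives total SS = tr G =
Σ_{i<j} d²_ij / n. For the nested design matrices X_0 (intercept) ⊂ X_1
⊂ … in the model's term order, the sequential (Type I) SS of term k is
tr[(H_k − H_{k−1}) G], with H the SVD-based orthogonal projector; df_k
is the rank increment. Pseudo-F_k = (SS_k/df_k)/(SS_res/df_res);
p-values come from freely permuting sample identities (rows/columns of
D), p = (1 + #{F* ≥ F_obs})/(1 + n_perm), on the discrete grid with
minimum 1/(n_perm+1). Sequential SS in the printed term order is the
convention of the analysis this re-implements; the order of terms is
therefore meaningful.

Degenerate designs are reported, not crashed on: a term aliased with
earlier terms (rank increment 0 — e.g. O×D×N reduces against the
intercept+O+D+O×D span only through the CEWAFN column) gets 0 df and no
test; a saturated model (residual df 0 — the RNA side of the default
layout, where 23 cells meet a 22-df model) reports NaN F/p with a note;
an all-zero distance matrix (e.g. MNTD when every taxon occurs in every
sample) reports "no test". On Euclidean distance matrices the pseudo-F
is algebraically the classical ANOVA F, which the tests verify to 1e-9
against an independent ANOVA, and the type-I error at α = 0.05 is
checked against its binomial confidence band under the null.

t enters as a categorical factor (one level per timepoint) by default,
matching a multi-level microcosm time course; `time_linear` collapses it
to one ordinal column.

## The synthetic-data generator

Each (treatment, timepoint) cell draws a latent DNA composition
p ~ Dirichlet(c · b), where b is the base abundance vector adjusted by
the abundance fold-changes of effects active in that cell (then
renormalized) and c (default 500) is the single overdispersion knob —
larger c, less cell-to-cell compositional noise. 16S replicates are
independent multinomial draws from p at the 16S depth; the RNA library
is one multinomial draw from the RNA composition q, in which every
effect taxon's fraction is exactly 2^L times its DNA fraction and only
the unaffected complement is rescaled to keep q on the simplex. This
exact-ratio construction (rather than dividing the whole vector by its
sum) is deliberate: it makes the planted L the true value of the
estimand for the effect taxon, so estimator bias can be measured
cleanly; the complement's shared rescaling is the compositional price
and is visible as a small common offset in that cell's other taxa.

Defaults mirror the study design: treatments BC/DISP/WAF/CEWAF at
t0..t4 and CEWAFN at t0/t1/t4; triplicate 16S and a single RNA library
per cell (23 RNA + 69 16S libraries); depths 10⁵ (10⁴ in the pipeline's
quick configuration); a 16-genus toy community spanning the
hydrocarbon-degrading and methylotrophic genera prominent in such
experiments, with planted defaults of a dispersant-driven *Colwellia*
bloom, an oil-only *Marinobacter* bloom, a late *Kordia* response and
±2⁴ RNA enrichments. The generator also emits a matching toy taxonomy
(domain→genus) and a random binary tree (sequential pair joins,
exponential branch lengths, mean 0.5, floored at 0.01).

What it does *not* emulate: taxon absence patterns (at these depths
every taxon is observed in every library, which is why the 16S-side
MNTD matrix can be identically zero), annotation error, library-size
variation, phylogenetic signal in the planted effects, and functional
(gene-level) structure. Passing tests therefore demonstrate correctness
of the estimators under a clean compositional count model, not
robustness to annotation noise or sparsity.

## Numerical choices

* Symmetry/normalization tolerance 1e-9 absolute throughout; exact
  integer arithmetic in merge aggregation.
* Projector ranks via SVD with relative tolerance 1e-8; PCoA positive
  eigenvalues via relative tolerance 1e-12.
* The p-value counts permutations with F* ≥ F_obs (ties count toward
  the p-value, the conservative convention).
* All stochastic components run off `numpy.random.default_rng` seeds;
  the pipeline derives per-stage seeds from the config seed by fixed
  small offsets, and two runs with the same config are byte-identical.
* Problem sizes in the test-suite simulations (depth 10⁴–10⁵, 199–999
  permutations, 500 null replicates, ~200 random oracle instances) were
  chosen as the smallest sizes at which the tested contracts are sharp
  (recovery bias ≪ the ±0.3 band, binomial CI width ~±0.02).

## Known limitations

* The merge's retention statistic is the subtree abundance in the input
  table; labels absent from the reference are only usable under the
  bucket policy.
* Negative "R²"-like quantities reported by some adonis-style analyses
  cannot arise here: R² = SS_term/SS_total with sequential SS, which is
  nonnegative for Euclidean-embeddable inputs (tiny negatives are
  possible for strongly semi-metric inputs and are reported as-is).
* The RNA side of the default layout has no replication, so its
  PERMANOVA is saturated and reported untestable; inference rides on
  the replicated 16S matrices. A layout with replicated RNA libraries
  is one config edit away.
* MNTD on dense communities (all taxa everywhere) is identically zero;
  this is a property of the metric, surfaced rather than masked.
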