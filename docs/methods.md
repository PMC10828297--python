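# Methods

This note records the models, parameter choices and numerical conventions
behind `gerosig`, and what the synthetic benchmarks do and do not
demonstrate.

## Analysis model

The pipeline treats each differential-expression contrast as an opaque
signature: a vector of per-gene log2 fold-changes with raw and BH-adjusted
p-values, addressed by study / contrast / organ-or-cell-type / modality /
role metadata.  No DE model is refit; externally supplied FDR columns are
trusted as-is (matching the practice of adopting original-study DEG
calls), and only a missing FDR column is filled by Benjamini–Hochberg
adjustment of the raw p-values.

### DEG selection

A gene is differentially expressed iff `2**|log2FC| > 1.25` **and**
`FDR < 0.05`, both strict.  The fold-change rule is evaluated on the
linear scale; a linear-FC input dialect is converted to log2 at read time.
Whether the published ">" was meant inclusively at exactly 1.25 is
unverifiable; the strict reading is used and the boundary is pinned by a
test.  Gene symbols are case-sensitive by default with an optional
uppercase normalization for cross-species joins.

### Pairwise signature correlation

For each unordered context pair, Spearman ρ (average-rank ties) of the
log2 fold-changes over the genes that are DEGs in *both* contexts.
Design choices:

* "Shared DEGs" is the intersection of each context's own (either-sign)
  DEG set — the plainest reading of "shared".
* Pairs with fewer than 10 shared DEGs are excluded; the shared count is
  still reported so exclusions are auditable.
* P-values are two-sided (one- vs two-sided is unstated upstream); for
  n ≤ 10 the full n! permutation distribution is enumerated exactly
  (vectorized; the n = 10 table of 3.6 M permutations is built once and
  cached), above that the t approximation is used.  The boundary sits at
  the pair-exclusion threshold so every reported minimum-size pair is
  exact.
* Significance masking at raw p < 0.05, no cross-pair multiplicity
  correction (deliberately matching the upstream presentation rule).
* All context pairs are computed, including same-study pairs.

### Trend convergence

Per intervention and direction, a gene enters the intervention's DEG set
iff it is a direction-matching DEG in at least a minimum number of
*distinct* units: senolysis 1 organ, caloric restriction 2, reprogramming
2, heterochronic parabiosis 3 cell types.  The young-parabiont (Y-Par)
set uses the same ≥3-cell-type rule.  A gene DEG up in one organ and down
in another tallies toward both directions independently (up- and down-sets
are derived independently; no cancellation).  The global-aging reference
is a fixed signed input list, never recomputed.

Each trend intersects six sets (four intervention sets, Y-Par with the
opposite sign, aging reference with the opposite sign); the report keeps
genes in ≥ k sets (default 3).  A gene qualifying for both opposing
trends — possible when organs disagree — is flagged in a `conflict`
column rather than dropped or merged, since the upstream resolution is
unstated.

### Over-representation and rank scores

ORA is the upper-tail hypergeometric test with the stated filters: overlap
≥ 2, p < 0.01 (strict), fold enrichment = (overlap/list)/(set/background)
≥ 1.5.  The background is the gene-set library's universe intersected with
the genes measured in the context, avoiding detection-bias inflation;
BH-FDR is computed across all sets within one (context, direction) list,
mirroring per-list enrichment runs.  Up- and down-regulated lists are
always tested separately.

Rank scores count contexts with FDR < 0.01 (strict at the boundary):
1 point per whole-organ (bulk) context, 0.5 per cell-type-resolved
(single-cell) context — the fractional weight prevents one multi-cell-type
study from dominating organ-level evidence.  The weighted score is applied
uniformly to intervention and aging axes.  Trend–trend association is
Spearman over the union of pathways scored on either axis, absent items
scored 0; fewer than 3 items is an error rather than a meaningless
coefficient.

Chronic-inflammation maps score +1/−1 per up/down context, separately by
modality, giving integer 2-D coordinates bounded by the per-modality
context counts.

### Ambient-RNA DEG hygiene

Genes are prefiltered to those detected in > 1% of cells with > 1 UMI in
> 5 cells (all strict).  A DEG of cell type *c* is excluded iff it is a
rank ≤ 5 marker of a cell type ≠ *c* **and** rank ≤ 50 by dataset-wide
expression; rank thresholds are inclusive ("among the top 5" includes the
5th).  Marker definition and expression normalization are unspecified
upstream, so both are injectable inputs: markers arrive as a ranked table
from any upstream method, and "most highly expressed" is computed on
library-size-normalized totals over all cells (the ranking is dataset-wide,
not per cell type), with lexicographic tie-breaking for determinism.

### Transcriptomic clock

The clock is linear in transformed expression:
`age = intercept + Σ w_g · t_g`, with `t_g = log2(FPKM_g + 1)` by default
(pseudocount and log base are part of the model file).  Conventions:

* Coefficients are always an input file; no trained weights are bundled.
* UMI matrices get a fixed effective length of 10,000 bases for every
  gene before FPKM normalization.
* Mouse→human symbol mapping drops unmapped genes (logged); many-to-one
  collisions default to summing abundances (conserves counts; `max` and
  `error` policies available); one-to-many sources use the first listed
  target.
* Clock genes absent from a matrix are imputed at the transform of zero
  abundance — the conservative continuation of dropping unmapped genes.
* Scaling for presentation is configurable (z-score with the population-SD
  convention, min–max, or none), applied within panels; the upstream
  scaling method is unstated, so no default claims to match any published
  axis.
* Group comparison uses the exact two-sided Mann–Whitney rank-sum test
  when group sizes are small and tie-free (panel sizes here are small and
  the upstream test is unstated), the tie-corrected asymptotic form
  otherwise.

## Synthetic data

The generator emulates the *input* side of the analysis, not sequencing:

* A gene universe (default 1,000 genes, `G000001`…) with a signed aging
  program of 100 genes.  Effect magnitudes are
  `log2(1.5) + |Normal(0, 1)|` with random sign: the program stands in
  for a curated list of robustly differential aging genes, so every
  member carries an effect at least at the 1.5-fold scale — sub-threshold
  "program" genes would make membership unmeasurable by construction.
* Per context, `log2FC = role_sign × effect + Normal(0, σ)` with role
  signs +1 for aging, chronic inflammation and the young parabiont and −1
  for interventions; σ defaults to 0.2 (0.1 in the convergence benchmark).
  P-values are the two-sided normal tail of the observed log2FC under the
  noise model, so null genes are exactly uniform and FDR behavior is
  testable; no DE method is refit.
* The default study layout has 27 contexts: senolysis (2 organs), caloric
  restriction (3), reprogramming (2), parabiosis old- and young-parabiont
  contrasts (4 cell types each), bulk and single-cell aging references
  (3 + 3), and three inflammation models (3 bulk organs + 3 cell types).
* Gene sets: 30 sets of 40 genes, 12 planted (alternating up-/down-program
  coherent membership), planted fraction grading geometrically from 0.5
  to ~0.14 so enrichment strength spans saturated to borderline, as real
  pathway libraries do; the rest uniform null draws.  Background = the
  full universe.
* The marker fixture plants, per cell type, two ambient contaminants
  (top-2 markers of the next cell type, inside the top-50 expression
  block), two near-misses satisfying exactly one criterion each, own
  markers and clean genes, plus three rare genes that fail the prefilter.
  Counts are uniform across cells so the expression ranking equals the
  planted order exactly.
* Clock expression is constructed to invert the clock exactly: each
  sample's transformed profile is the convex combination of the two
  extreme admissible configurations whose readouts bracket the target
  age; with 1-kb lengths and a filler gene topping every library to 10⁶
  counts, FPKM equals the constructed abundance and the noiseless
  protocol returns the planted ages to machine precision.  Transformed
  values are floored at 1 so additive count noise (default SD 0.5)
  remains a small log-scale perturbation.  The test clock has eight genes
  with balanced coefficient signs (as trained clocks do — some genes rise
  and some fall with age); magnitudes are |Normal(0, 2)| floored at 0.75
  so the 30–70-year range is expressible with nonnegative abundances.

What the synthetic benchmarks show: the pipeline recovers planted sign
structure, set membership, contaminants and age shifts at realistic noise,
with calibrated nulls.  What they do not show: robustness to DE-model
misspecification, correlated noise between organs of one animal cohort,
batch effects, or homolog ambiguity beyond simple collisions — real inputs
carry all of these.

## Benchmark conditions and observed behavior

Problem sizes were chosen so the full suite runs in well under a minute of
compute per benchmark: sign structure uses 20 seeds × 21 non-CI contexts ×
1,000 genes (noise 0.2); convergence 20 seeds at noise 0.1; the clock 50
seeds of 5-vs-5 panels with a planted −10-year shift.  Under these
conditions the suite observes: every significant intervention × aging
correlation negative and every aging × aging correlation positive in all
seeds (mean ρ ≈ ∓0.96); both trend rank-score correlations positive in
≥ 95% of seeds; convergent-gene sensitivity 1.0 with zero false-discovery
proportion; exact ambient-contaminant recovery; and the planted
rejuvenation detected with exact rank-sum p < 0.05 in all seeds.  These
numbers are recomputed, not asserted, by `scripts/acceptance.py`.

## Known limitations

* The exact permutation p-value at n = 10 allocates a ~150 MB temporary
  for the permutation table on first use (cached thereafter).
* `pathway_rank_scores` weights by modality (bulk = organ = 1.0,
  single-cell = cell type = 0.5); a study mixing cell-type-level bulk
  contexts would need explicit weights.
* The clock-expression constructor requires target ages inside the range
  the clock can express with nonnegative abundances; it reports the range
  when asked for anything outside it.
* `run_pipeline` expects the dataset-directory layout written by
  `gerosig.synthetic.write_dataset`; assembling the same layout from real
  exports is supported but not automated.
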