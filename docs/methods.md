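# Methods

## Model and procedure

`mirsm` infers mRNA-related miRNA sponge modules from three inputs: a
miRNA expression matrix and an mRNA expression matrix over the same
samples, and a (miRNA, mRNA, context++ score) summary of sequence-level
target predictions.  The pipeline has four stages.

**Preprocessing.**  Rows missing in more than half of the samples are
dropped (strict `>`), remaining gaps are filled by k-nearest-neighbour
imputation (k = 10; Euclidean distance over co-observed samples, via
scikit-learn's `KNNImputer` with entities as the imputation rows),
rows without a usable gene symbol (empty or `?` by default) are removed,
and replicate rows are averaged.  Imputation runs after the missing
filter and before replicate averaging; both the order and k are
configurable.  The two matrices must profile the same sample set; they
are aligned by reordering, and any other mismatch is an error.

**Regulatory scores.**  `S = a·W + b·T`, with `W` the Pearson
mRNA × miRNA correlation matrix and `T` the dense context++ matrix
(0 where no record exists, values clamped to [−1, 0]).  `a` and `b`
default to 0.5 — equal weight to expression and sequence evidence — and
are not renormalised, so the attainable range of `S` is
[−a − b, a] = [−1, 0.5] at the defaults.  Pairs with `S ≤ s` are
reconstructed miRNA–target edges.  The default `s = −0.3` reflects the
conventional magnitude at which a negative sample correlation becomes
significant at the 5% level for cohorts of this size; because `T = 0`
for unrecorded pairs, an edge can be reconstructed from expression
evidence alone.  Decreasing `s` (more negative) can only shrink the
edge set — the reconstruction is monotone in `s`, which propagates to a
monotone interaction count downstream.  Zero-variance expression rows
get correlation 0 rather than NaN.

**Plaid biclustering.**  `S` is decomposed greedily into layers
`Y ≈ θ0 + Σ_k (μ_k + α_ik + β_jk)·ρ_ik·κ_jk` with binary row/column
memberships:

* the background `θ0 = μ0 + α_i0 + β_j0` is fitted by Tukey median
  polish.  A least-squares background lets a minority block drag the row
  and column means, leaving compensating stripes in the residual that
  later masquerade as layers; medians are immune to a minority block.
* each layer starts from sign splits of the top two singular vector
  pairs of the residual (8 candidate starts; the best post-pruning layer
  wins).  Two pairs are tried because equally deep disjoint blocks make
  the leading singular pair rotationally degenerate: a single-vector
  start merges the blocks into a union layer that release pruning then
  destroys, while the second vector's sign split separates them.
* effects and memberships alternate for `iterations` = 10 cycles:
  effects by two-way least squares given memberships, then memberships
  by binary least squares (a row joins iff joining reduces the layer's
  residual sum of squares; an exactly-zero gain resolves to
  non-membership, keeping layers sparse).
* member rows/columns whose within-layer sum of squares the layer
  explains at a fraction below `row_release` = `col_release` = 0.7 are
  released.
* a layer is accepted only if its explained sum of squares exceeds that
  of a fresh fit on each of `shuffles` = 3 row-wise permuted copies of
  the residual; on unstructured residuals release pruning usually
  empties the candidate layer first, so pure-noise inputs yield zero
  layers.  Layers with fewer than two rows or columns are rejected
  outright (a module needs at least two mRNAs to contain a sponge pair).
  Fitting stops at the first rejected layer or at `max_layers` = 20.
* after each accepted layer, one backfitting cycle re-estimates the
  background and all layer effects jointly on the data minus the other
  components, so the residual sum of squares is non-increasing across
  layers.

All randomness (the permutation shuffles) comes from `random_state`;
fits are bit-reproducible given a seed.  Rows are mRNAs and columns are
miRNAs throughout.

**Sponge inference.**  Within each bicluster, every unordered mRNA pair
is scored with (i) the upper-tail hypergeometric probability of sharing
`x` reconstructed miRNA regulators, with `M` and `K` the two mRNAs' full
reconstructed target-set sizes and `N` the number of miRNAs in the
preprocessed dataset (not the bicluster's column count); and (ii) the
Pearson correlation with its two-sided t-distribution p-value (n − 2
df).  Pairs pass at raw `p < 0.01` on both tests with `r > 0`;
Benjamini–Hochberg adjustment of both p-value families is available
behind a flag but off by default, matching the usual dual-raw-threshold
procedure.  Candidate pairs present in the supplied TF–target list (in
either orientation — a sponge pair is unordered) or PPI list are
removed, then mRNAs left without interactions are dropped.  Modules with
no interactions are discarded.  Whether sharing should be counted over
all miRNAs or only the bicluster's columns is genuinely open; we use all
miRNAs, consistent with the definition of `N`.

## Baselines

All three baselines search the unrestricted mRNA-pair universe and by
default take each mRNA's regulator set from the *putative* binding table
rather than reconstructed edges, the convention of the pairwise and
partial-association literatures they represent.

* **PC** keeps pairs passing the same dual hypergeometric/correlation
  tests, with no biclustering and no TF/PPI filtering.  Any module's
  interaction set is therefore contained in PC's result when both use
  the same target sets and cutoff.
* **SPPC** additionally computes the sensitivity `r − r_partial`, where
  the partial correlation conditions jointly on the full set of shared
  miRNAs via the precision matrix of the joint correlation matrix
  (a per-miRNA averaging variant is available); pairs below the 0.3
  cutoff are dropped, so SPPC ⊆ PC by construction.  Pairs whose
  conditioning set reaches n − 2 variables are skipped with a warning.
* **Hermes** is a reduced re-statement of the conditional-mutual-
  information approach, not a reproduction of the published tool: for
  each shared miRNA z it estimates `ΔI = I(m1; z | m2) − I(m1; z)` by
  equal-frequency binning (4 levels per variable), calibrates it by
  permuting m2's sample labels, and combines the per-miRNA p-values with
  Fisher's method.  With B permutations the attainable p-values are
  multiples of 1/(B+1), so the test is exact under exchangeability; the
  binning bias (≈ (bins−1)²/2n for the plug-in estimator) cancels
  between observed and permuted statistics.

## Synthetic data

The generator emulates a matched tumour expression cohort: 72 samples,
60 miRNAs, 150 mRNAs, and two implanted modules of 8 miRNAs × 15 mRNAs
by default.  Each module has a latent driver (standard normal per
sample); module miRNAs load on it with co-expression weight w = 0.5 and
unit marginal variance, and each module mRNA is
`baseline − strength · (mean module miRNA profile) + σ·ε` with
strength 1 and σ = 0.3.  Module miRNAs are modelled as co-expressed —
a cluster of miRNAs acting on the same targets is typically
co-regulated, and fully independent miRNAs would make the mean profile
(and hence each individual miRNA) only weakly coupled to its targets at
realistic module sizes.  Writing `v = w + (1 − w)/k` for a module with
k miRNAs, the implied population correlations are

* mRNA vs single module miRNA: `−strength·v / √(strength²·v + σ²)`
  (≈ −0.70 at the defaults),
* mRNA vs mean miRNA profile: `−strength·√v / √(strength²·v + σ²)`
  (≈ −0.93),
* mRNA vs mRNA within a module: `strength²·v / (strength²·v + σ²)`
  (≈ 0.86),

which the tests verify by Monte Carlo at n = 5000.  The binding table
records a Uniform(−0.8, −0.2) score for every true (module miRNA,
module mRNA) pair plus 10% decoy records on random non-true pairs; 10%
of the true within-module sponge pairs are planted into the TF edge
list and a disjoint 10% into the PPI list, alongside random background
edges among non-module genes, to exercise the direct-interaction
filter.  Everything is reproducible given a seed and round-trips
through the package's TSV readers.

What the generator does *not* emulate: count noise and library-size
effects (expression is additive Gaussian, as appropriate for normalised
level-3 data consumed by Pearson machinery), tumour/normal batch
structure, overlapping modules, and miRNAs targeting genes across
modules.  Passing tests therefore demonstrate correct mechanics and
recoverability under the stated generative model, not performance on
real cohorts.

## Problem sizes and numerical choices

The test suite and behavioural checks run at the generator's default
scale (150 × 60 score matrices, 72 samples) and a reduced fixture
(60 × 24, 48 samples) chosen so a full pipeline run takes well under a
second; the plaid recovery checks use 60 × 40 matrices with a 15 × 10
implanted block at a shift of 5 noise SDs, averaged over 20 seeds.
Hypergeometric p-values are computed through scipy's survival function
(not 1 − cdf) and match exact rational arithmetic to better than 1e−10
over the full N ≤ 30 grid.  Duplicate binding records collapse to the
most negative score; records with score ≥ 0 are dropped at load.  Ties
in binary least squares resolve to non-membership; ties among candidate
layer starts resolve to the first candidate in a fixed order.

## Known limitations

* Plaid layers absorb correlated "bystander" columns: miRNAs whose
  score columns co-vary with a module (through the module genes' mutual
  correlation) can join its layer, so reported module miRNA sets may be
  supersets of the implanted ones.  Sponge (mRNA) sets are unaffected —
  the hypergeometric and correlation tests re-filter rows.  For small,
  shallow modules the same mechanism can merge two modules' gene sets
  into one layer.
* The Hermes baseline approximates the cited conditional-mutual-
  information method; its statistic direction (conditioning on the
  partner mRNA) is one of several published variants.
* p-values are used raw at 0.01 by design; with very large biclusters
  the number of tested pairs grows quadratically and the optional BH
  flag may be preferable.
* GO/KEGG enrichment, differential-expression calling, and curated
  disease gene lists are out of scope; `gene_list_overlap` accepts any
  user-supplied list for simple overlap percentages.
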