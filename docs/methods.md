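# Methods

## The model

`consica` assumes the standard linear latent-factor model of transcriptomics:
an observed gene × sample expression matrix **X** (already normalized, log
scale) is generated by a small number of statistically independent
transcriptional programs,

    X = A · S + ε,

where the rows of **S** (components × samples) are the activity patterns of
latent transcriptional components across samples, **A** (genes × components)
is the *mixing matrix* whose entry *a<sub>gc</sub>* is the effect of
component *c* on gene *g*, and ε is measurement noise. Independent component
analysis can identify **S** up to sign and permutation provided the sources
are non-Gaussian; transcriptional programs measured across heterogeneous
sample compendia are strongly super-Gaussian (most samples show little
activity of any given program, a few show a lot), which is what makes the
model workable in practice.

A gene's row of **A** is its *transcriptional regulatory barcode*: a compact
description of which latent programs regulate it and how strongly. The
package's central claim of use is guilt-by-association at the barcode level:
genes whose barcodes resemble the *average* barcode of a gene set's members
are candidate members of that set, even when their raw expression
correlation with any individual member is weak.

## Pipeline stages

### Sample QC

The first principal component of the sample–sample Pearson correlation
matrix of a large compendium captures a platform-wide signature that almost
all good samples share. We project the raw matrix onto that eigenvector to
get the signature's gene-space image and discard samples whose expression
profile correlates with it below `r_min` (default **0.8**). The component's
sign is fixed so the majority of sample correlations are positive, making
the filter deterministic. On synthetic data with no platform signature this
filter is inappropriate and can be disabled (`qc_enabled = false`).

### Whitening

Genes are centered across samples and the gene–gene covariance is
eigendecomposed (via SVD of the centered matrix; divisor *n*−1). The
smallest number of leading axes whose cumulative explained-variance fraction
reaches `var_threshold` (default **0.90**) is retained, and the retained PC
score vectors are rescaled to zero-mean, unit-variance, exactly decorrelated
*whitened variables*. Loading-column signs follow a
largest-|loading|-positive convention so the basis — and everything
downstream — is invariant to the row order of the input.

### Consensus ICA

FastICA (log-cosh contrast, symmetric/parallel extraction, sklearn's
fixed-point implementation) is run `n_runs` times (default **25**) on the
whitened variables with run seeds derived from one global seed; the number
of components extracted per run equals the number of whitened variables.
FastICA's solutions vary across restarts, so components are matched across
runs: the first converged run seeds one cluster per component (ordered by
descending signal variance), and each later run contributes at most one
component per cluster, greedily, when its absolute Pearson correlation to
the cluster's reference exceeds `match_r` (default **0.98**), with sign
alignment to the reference. A consensus component is retained only when its
cluster spans at least `min_match_runs` runs (default **13**, i.e. a
*credibility index* — run coverage / `n_runs` — above 0.5). Retained
consensus components are the sign-aligned cluster means, renormalized to
unit variance. A run that fails to converge is retried once with a fresh
derived seed and otherwise excluded from matching while still counting in
the credibility denominator — the conservative choice.

Finally the components are put in canonical order (descending explained
variance over the whitened variables) with canonical sign (the
largest-|weight| whitened variable loads positively). FastICA's raw
component order is arbitrary; without this the output would depend on
numerically irrelevant details such as gene row order.

The gene-space mixing matrix is recomputed by least-squares projection of
the centered expression matrix onto the consensus sources (pseudo-inverse if
the sources are rank-deficient, with a warning).

### Barcodes and prediction scores

* **ICA path** — a gene set's barcode is the component-wise mean of its
  members' mixing-matrix rows; similarity between a gene barcode and a set
  barcode is the **distance correlation** (classical biased V-statistic;
  degenerate inputs map to 0). A member gene is *not* excluded from its own
  set's barcode (leave-in); a leave-one-out flag exists for sensitivity
  analysis.
* **PCA path** (the comparator used by eigenvector-based predictors) — a
  set's barcode is the per-principal-axis Welch-T profile of member versus
  nonmember loadings; similarity is the Pearson correlation with the gene's
  loading row.

Observed similarities are calibrated by permutation: for each (gene,
set-size) pair, `n_perm` (default **1000**) random same-size gene sets are
drawn, their barcodes computed by the same rule, and the similarity to the
gene's barcode collected. A Gaussian KDE with Silverman's rule-of-thumb
bandwidth smooths the samples, and the p-value is the analytic
Gaussian-mixture survival probability above the observed value — never
exactly 0 or 1 because the kernel tails are unbounded. The prediction score
is Z = Φ⁻¹(1 − p), evaluated through log-space tail probabilities
(`ndtri_exp` on whichever tail is numerically small) so it is finite and
strictly monotone for any observed value. The PCA path can instead use the
parametric one-sided correlation t-test (`p_mode = "parametric"`), the
convention of the eigenvector-based predictors; the permutation default
makes the two paths' Z-scores directly comparable.

Because the null depends only on the querying gene and the set's size, nulls
are cached per (gene, set size). The permutation stream is keyed on the
*gene identifier* (stable CRC32) and the random sets are drawn from a
canonically sorted gene order, so cached and per-pair scoring agree exactly
and the score table is bit-identical under any row reordering of the inputs.

### Evaluation statistics

* Per-set median member score and median score of *unannotated* genes
  (genes in no set of the collection); a collection-level Mann–Whitney AUC
  (midrank U/(n₁n₂), tie-corrected normal p) compares the two median
  vectors.
* Method comparison: per-set delta = ICA member median − PCA member median;
  positive deltas are "ica-improved", negative "pca-improved", exact zeros
  "tied" (kept as their own class).
* Version-update: for sets that gained members between two collection
  versions, the newly added ("updated") members' median scores under
  barcodes built from the old versus the new membership.
* Multifunctionality: Score(g) = Σ over sets containing g of
  1/(N_in · N_out), with N_in the set size and N_out the complement size in
  the universe; the pan-collection score is the sum of per-collection scores
  over a shared universe. The association between a collection's
  multifunctionality vector and each set's score column is reported as a
  distance correlation.

### Clustering and networks

Gene barcodes are clustered with Ward agglomeration (the squared-update
"ward.D2" convention, i.e. scipy's `ward` on the raw dissimilarities) at
1 − distance correlation, dendrogram cut at `cut_height` (default **2.5**);
prediction-score profiles likewise at 1 − Pearson correlation, default cut
**0.8**. Cut heights scale with dataset size — the defaults are sensible for
compendium-scale gene counts, and small fixtures need proportionally smaller
cuts. Clusters outside the 10–500 size range are flagged, not re-cut: a
generic dataset need not admit a cut satisfying the range. Per-cluster
diagnostics: *transcriptional similarity* (median pairwise distance
correlation of member barcodes; undefined for singletons) and
*predictability* (median over members of each member's maximum prediction
score across all sets), plus the across-cluster Pearson correlation of the
two. Co-functionality is the absolute Pearson correlation between two genes'
prediction-score vectors (input capped at 300 genes by default); the
thresholded graph is exported as GraphML or a TSV edge list with
deterministic node/edge order, without layout computation.

## The synthetic-data generator

`generate_expression` draws **X = A·S + ε** with k unit-variance
super-Gaussian source rows (Laplace by default, excess kurtosis 3; a
two-component Gaussian scale mixture and a Gaussian negative control are
also available), a mixing matrix with dense N(0, background_sd²) background
loadings (default 0.05) plus a `loading_block` (default 1.0) added for each
planted set's members on its designated column, and N(0, noise_sd²) noise
(default 0.1). The reference condition used throughout the tests and the
acceptance script is 300 genes × 600 samples, k = 6, planted sets of
size 20.

What the generator does *not* emulate: batch structure, probe effects,
count noise, overlapping/hierarchical gene sets, and heterogeneous per-gene
effect sizes within a set. Passing tests therefore demonstrate that the
machinery is correct and well calibrated under the linear super-Gaussian
model, not that real compendia satisfy that model.

## Numerical and design choices

* **Distance correlation resolution.** A barcode with k components gives the
  V-statistic only k "observations"; for very small k the statistic
  saturates toward 1 (random length-4 vectors have median dCor ≈ 0.73).
  Experiments that compare nearby barcodes need k ≥ ~8, and association
  diagnostics need a few hundred genes before the finite-sample floor
  (~n^−1/2) drops below 0.1. The version-update experiment defaults
  (k = 8 components, sets of 12, 240 genes, 60% "old" membership,
  n_perm = 300, 20 replicates) were chosen so both the statistic and the
  barcode-estimation error have resolution; with large homogeneous sets the
  60% and 100% barcodes estimate the same mean almost exactly and the
  comparison carries no signal.
* **Sign symmetry.** Prediction scores are invariant to a *global* sign flip
  of all components and to joint component permutation. They are *not*
  invariant to flipping a single component's sign: distance correlation
  treats the barcode as unordered scalar observations, and negating one
  coordinate of both vectors changes the pairwise distance matrices. The
  canonical sign convention removes this ambiguity from the pipeline's
  output.
* **Degenerate nulls.** Silverman's bandwidth of an (almost) constant null
  sample is 0; it is floored at 10⁻³ so the smoothed tail stays defined
  (e.g. when the permuted set size equals the whole universe).
* **Zero-variance groups** in a Welch-T barcode get statistic 0 with a
  warning; constant profiles get co-functionality 0 off-diagonal and 1 on
  the diagonal.
* **Determinism.** One global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence`; reruns with identical configuration produce
  byte-identical score tables, and every pipeline artifact records a hash of
  the configuration.
* **GMT harmonization order.** Set members are intersected with the declared
  universe *before* the 10–500 size filter, so a set is judged on its usable
  members; the filter is idempotent.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
decompositions of a few hundred genes × a few hundred samples, 25 ICA
restarts, permutation nulls of 300–1000 draws, 2000 calibration pairs, and
20 version-update replicates. These sizes keep every property measurable
with comfortable statistical margins while completing in about a minute
each for the suite and the script.

## Known limitations

* The consensus matcher is a greedy reference-run scheme; it does not
  perform full all-pairs cluster-quality diagnostics (ICASSO-style) beyond
  the credibility index.
* The sample-QC filter presumes a dominant shared signature; it is not
  meaningful for structure-free or small data.
* Headline numbers from compendium-scale analyses (hundreds of components,
  AUC ranges over thousands of real gene sets) are out of scope: they
  require ~10⁵ real samples and curated collections, not the synthetic
  conditions generated here.
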