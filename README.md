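# consica

Consensus independent component analysis of gene-expression compendia and
guilt-by-association (GBA) prediction of gene set memberships.

## The problem

Gene set collections (GO, KEGG, Reactome, …) are incomplete, and classic
co-expression GBA is biased: a gene involved in several biological processes
is pulled toward whichever process dominates its expression profile. This
package addresses both by working in the space of *latent transcriptional
components* rather than raw co-expression. It is aimed at computational
biologists who have a large normalized gene × sample expression matrix and
one or more gene set collections in GMT format, and who want a ranked,
calibrated membership score for every gene–gene set pair.

## The method

Under the linear model **X = A·S + ε**, whitening by PCA on the gene–gene
covariance (keeping the leading axes explaining ≥ 90 % of the variance) is
followed by 25 restarts of FastICA. Components are matched across restarts
at |Pearson r| > 0.98, and a consensus component is kept only when it
reappears in ≥ 13 of 25 runs (*credibility index* > 0.5) — this suppresses
the restart-to-restart instability of ICA. Projecting the expression matrix
onto the consensus sources gives the mixing matrix **A**; a gene's row of
**A** is its *transcriptional regulatory barcode*.

A gene set's barcode is the mean of its members' rows. For every gene and
set, the distance correlation between their barcodes is compared against a
permutation null (random same-size gene sets), smoothed by a Gaussian kernel
density estimator, and reported as a Z-score:

    Z = Φ⁻¹(1 − p),   p = P(dCor ≥ observed | random membership).

A PCA comparator (per-component Welch-T set profiles, Pearson similarity,
permutation or parametric p) replicates the convention of eigenvector-based
predictors so the two strategies can be compared on equal footing.
Downstream modules compute multifunctionality diagnostics, member/nonmember
evaluation AUCs, gene-set version-update comparisons, hierarchical
clustering of barcodes and score profiles, and thresholded co-functionality
networks.

## Worked example

```python
import consica as ci
from consica.simulate import planted_collection
from consica.evaluation import evaluate_collection

# synthetic compendium: 6 independent Laplace programs mixed into 300 genes,
# with six planted 20-gene sets sharing mixing structure
X, truth = ci.generate_expression(n_genes=300, n_samples=600, k=6,
                                  set_size=20, noise_sd=0.1, seed=11)

basis = ci.whiten(X, var_threshold=0.90)
mm_w, sources, report = ci.run_consensus_ica(basis, n_runs=25,
                                             match_r=0.98,
                                             min_match_runs=13, seed=42)
MM = ci.recompute_mixing(X, sources, mm_w)

coll = planted_collection(truth, X.gene_ids)
table = ci.score_all(MM, coll, method="ica", n_perm=500, seed=7)
summary = evaluate_collection(table, coll)
```

This prints, via the obvious inspection statements:

```
whitened variables: 6 (explain 97.5% of variance)
consensus components: 6, credibility: 1.00-1.00
SET1 member median Z: 2.71
unannotated-gene median Z for SET1: -0.77
member vs unannotated AUC over per-set medians: 1.000 (p = 0.0051)
```

Six whitened variables suffice for the six planted programs; all six
consensus components reappear in every restart (credibility 1.0). Member
genes of a planted set score around Z ≈ 2.7 for their own set while genes
belonging to no set sit below zero, so the per-set member medians separate
perfectly from the unannotated medians (AUC 1.0).

The same flow is available from the shell:

```bash
consica simulate --genes 300 --samples 600 --k 6 --seed 11 --out sim
consica decompose sim.expression.tsv --out dec --seed 42 --no-qc
consica predict --mixing dec/mixing_matrix.tsv --collection sim.planted.gmt \
        --n-perm 500 --seed 7 --out scores.tsv
consica evaluate --scores scores.tsv --collection sim.planted.gmt --out eval.tsv
consica network --scores scores.tsv --threshold 0.5 --out net.graphml
```

or as one pipeline run, `consica run pipeline.cfg`, with a flat key–value
config file:

```
expression = sim.expression.tsv
gmt        = sim.planted.gmt
out_dir    = out/
seed       = 11
qc_enabled = false      # synthetic data has no platform signature
```

Every artifact carries a hash of the configuration; reruns with the same
config are byte-identical.

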