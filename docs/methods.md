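# Methods

## The screening model

`isodiverge` treats a gene-expression compendium as a collection of
independent datasets (experiments), each a genes × arrays matrix of
log-scale values with missing entries. All inference is within-dataset:
correlations computed inside a single experiment are comparable across
array platforms after simple normalization, whereas absolute expression
levels are not. The screen deliberately tests only *negative* correlation.
Paralogous genes often cross-hybridize on microarrays, which inflates
positive correlation; a negative-only test is robust to that artifact.

For a pair (x, y) in dataset *d*, the Pearson correlation
*r* over the *N* jointly observed arrays (pairwise-complete observations)
is mapped to the Fisher-transformed statistic *z* = atanh(*r*)·√(*N* − 3),
standard normal under independence, and the anticorrelation p-value is the
lower normal tail Φ(*z*). Records with *N* < 6, a gene absent, or zero
variance are skipped rather than imputed. *r* is clamped to
±(1 − 10⁻¹²) before atanh so perfect correlations give large finite *z*;
p-values are floored at 10⁻³⁰⁰ so they remain in (0, 1].

### q-values

P-values are corrected with the Storey–Tibshirani q-value: π₀ is
estimated on the λ-grid {0.05, …, 0.95} via
π₀(λ) = #{p > λ}/(m(1 − λ)), smoothed with a cubic polynomial and
evaluated at λ = 1, clipped to [1/m, 1]; fewer than 20 p-values fall back
to π₀ = 1 (pure Benjamini–Hochberg), and π₀ can be forced to 1 for
oracle comparisons. The default correction family is *per pair class*
(isozyme, complex, pathway, random records corrected separately), because
class-specific anticorrelation rates are compared downstream; global and
per-dataset families are available via `add_qvalues(..., family=...)`.

### The B matrix and classification

*b<sub>m,n</sub>* = 1 iff pair *m* has q ≤ q\* (default 0.1, inclusive)
and *r* < 0 in dataset *n*; untested combinations are 0. The per-pair
anticorrelation proportion *p<sub>m</sub>* is the row mean over **all**
datasets, so pairs missing from many datasets are conservatively diluted.

The dosage-vs-divergence classifier is a logistic regression of class
(complex = 1, random = 0) on *p<sub>m</sub>*, fitted by maximum
likelihood with a weak L2 ridge (strength 10⁻⁴, intercept unpenalized).
The ridge is inert on non-separable data (the fit matches the
unpenalized MLE to ~10⁻² in the coefficients) and caps the slope when
small catalogs are perfectly separated, keeping probabilities inside
(0, 1). Labels use an inclusive 6:1 odds threshold: random-like iff
P(C)/(1 − P(C)) ≤ 1/6, complex-like iff ≥ 6, else ambiguous. An
alternative probability cutoff pair (0.83/0.17, ≈ 5:1) can be selected
via the `odds_threshold` argument.

PAM clustering of B's binary rows uses Manhattan (= Hamming) distance.
Instances with at most 10⁴ candidate medoid sets are solved exactly by
enumeration; larger instances use the classical build + swap heuristic
with index-order tie-breaking, so results are deterministic.

## Dataset clustering

Experiments applying similar perturbations disturb similar genes, so each
dataset is summarized by its per-gene SD vector (ddof = 1 over observed
arrays). Preprocessing order: drop genes then datasets with > 70% missing
entries; KNN imputation with 10 neighbor genes (nan-Euclidean distance,
unweighted neighbor mean, via scikit-learn's `KNNImputer`); per-dataset
offset of half the smallest *positive* SD (constant genes have SD 0 and
must not set the offset) followed by natural log (the base is irrelevant
after z-normalization); column z-normalization then row z-normalization,
applied literally in that order, so the final matrix has unit-variance
rows but not columns.

Consensus k-means draws 125 subsamples of 80% of genes and 80% of
datasets, clusters each with Lloyd k-means (10 restarts, greedy
farthest-point initialization from a seeded random first center,
convergence on stable assignments or 300 iterations), and records the
fraction of co-draws in which two datasets co-cluster. Never-co-sampled
pairs get consensus 0 (vanishingly rare at these settings). The consensus
matrix is cut by average-linkage hierarchical clustering on 1 − consensus
into k groups. RSS(k) is computed on the **full** processed matrix
(squared Euclidean distance of each dataset vector to its cluster
centroid), and AIC(k) = RSS(k) + 2·M·k with M the number of genes; the
smallest k wins ties. Every random choice derives from a single seed, and
each candidate k uses an independent seed-derived stream so single-k runs
reproduce.

## Cluster association

For each pair and cluster C with at least 1 in-cluster and 3
out-of-cluster records (combinations below these floors are skipped as
untested, not errors): criterion 1 is mean(z<sub>in</sub>) < 0, strict at
the boundary; criterion 2 is the one-tailed rank-sum test of
z<sub>in</sub> stochastically smaller than z<sub>out</sub>. Rank-sum
p-values are exact permutation enumerations whenever
C(n<sub>in</sub>+n<sub>out</sub>, n<sub>in</sub>) ≤ 20 000 (which covers
every instance with both samples ≤ 8, and handles ties exactly);
otherwise the normal approximation with tie and continuity correction is
used. All tested pair × cluster p-values form a single q-value family —
including criterion-1 failures, which simply cannot be flagged — and
association requires both criteria with q ≤ 0.1.

## Catalog filtering and enrichment

The five catalog criteria are declarative booleans supplied with each
candidate (the package does not resolve organism databases): (i) same
reaction, (ii) small-molecule substrates/products, (iii) same cofactor
preference, (iv) reaction confined to one compartment, (v) proteins
annotated to the same compartment. Filtering records every violated
criterion and is idempotent. Pathway enrichment uses the two-tailed
Fisher exact test by the probability-mass convention (sum of
hypergeometric outcomes no more probable than the observed table), with
Bonferroni–Holm adjustment across exactly the user-listed categories.

## Metabolomics

Intensities are divided by per-sample total cell volume, log2-transformed
(log2 chosen for fold-change units; the base only scales the axis),
detrended per metabolite by OLS on run order (keeping residuals ε, which
are exactly orthogonal to run order), and referenced by subtracting the
per-metabolite mean residual of a selected reference condition. Paired
comparisons take each mutant sample against the wild-type sample run
immediately before it and report linear-scale ratios 2^Δlog2.

Mass-isotopomer correction builds the forward matrix A whose column j is
the measured pattern of the species with j nominally labeled carbons:
the convolution of Binomial(j, 1 − impurity) (labeled carbons are ¹²C at
the ~1% tracer impurity rate) and Binomial(n − j, 0.011) (unlabeled
carbons are ¹³C at natural abundance). Observed fraction vectors are
corrected by ordinary least squares, with negative solutions clipped to
zero and the vector renormalized to sum 1 — the minimal positivity
repair. The correction operates on fraction vectors, not raw ion counts.
Noise-free round trips recover mixtures to ~10⁻¹⁵ for up to 12 carbons.

## The synthetic compendium

Defaults: 4 dataset clusters × 6 datasets, 12–24 arrays each, 180 genes,
unit-SD Gaussian log-expression. Planted structure:

* **Divergent pairs** (5 per cluster, catalog class "isozyme"): inside
  their target cluster, x = +βf + ε and y = −βf + ε with a per-array
  standard-normal factor f and β = 1.5, giving within-cluster
  r = −β²/(β² + 1) ≈ −0.69; independent noise elsewhere. The per-array
  independent factor is the simplest model with this closed form.
* **Coexpressed pairs** (10, class "complex"): same-sign loadings in
  every dataset — the dosage-like behavior of co-complexed genes.
* **Random pairs** (20, class "random"): a weaker shared factor
  (loading 1.0) whose two loading signs are re-drawn independently per
  dataset, so these pairs are sometimes correlated and sometimes
  anticorrelated with no cluster alignment. This reproduces the empirical
  ordering seen in real compendia — random gene pairs show more background
  anticorrelation than members of the same complex — which is what makes
  the complex-vs-random classifier meaningful. Setting
  `random_pair_loading = 0` turns them into pure noise; the null-FDR and
  exchangeability checks use that configuration.
* **Signature genes** (15 per cluster): noise SD multiplied by 3 inside
  their cluster's datasets, giving each cluster the variance fingerprint
  the dataset clustering detects.
* Missing values completely at random at rate 0.02 (KNN imputation
  downstream assumes uninformative missingness; no informative model is
  provided).

These sizes were chosen once as a desk-scale analog of a real compendium:
large enough that a divergent pair's in-cluster evidence (|z| ≈ 3.5 per
dataset) and the signature-variance signal are clearly detectable, small
enough that a full screen runs in seconds. What the generator does *not*
emulate: platform heterogeneity and dye bias, cross-hybridization
(mitigated in the method by testing only negative correlation),
non-Gaussian expression distributions, correlated missingness, unequal
cluster sizes, and pairs spanning more than two genes. Passing the
recovery suites therefore demonstrates the pipeline's correctness and
calibration under its stated model, not performance guarantees on any
particular real compendium — in particular, the number of clusters chosen
on real data is data-dependent.

The fixture catalog (77 candidates of which 24 fail only the
compartment criterion, plus five decoys failing criteria (i)–(iv)) and
the pathway table (632 reactions, 51 isozyme-catalyzed; 12 glycolysis/
gluconeogenesis/fermentation reactions with 8 flagged) are frozen in
code; per-category counts outside glycolysis are synthetic.

## Numerical and design notes

* Determinism: every stochastic step takes a `numpy` Generator seed; the
  pipeline fans one global seed out to stages by fixed offsets (seeds kept
  below 2³¹).
* Exact rank-sum enumeration is bounded by combination count rather than
  sample size alone, since n_in = 8 with a large n_out is combinatorially
  infeasible; beyond the bound the corrected normal approximation is
  accurate to a few percent.
* Dataset rankings break column-sum ties lexicographically by dataset id;
  AIC ties go to the smaller k; PAM ties to the lower row index.
* Classification thresholds are inclusive with a 10⁻⁹ relative tolerance
  to absorb float round-trip error at the odds boundary.
* The hierarchical display ordering of the q-intensity matrix (uncentered
  Pearson) is cosmetic and not part of inference; it is not implemented.

## Known limitations

* The screen assumes pre-logged, within-dataset-comparable expression
  values; raw-intensity normalization and probe-to-gene mapping are out
  of scope.
* q-value family choices (per class for B, single family for
  associations) are defensible conventions, not uniquely determined;
  both are configurable.
* Consensus k-means RSS is computed on the full matrix; computing it on
  subsamples would shift the AIC curve but rarely the argmin at these
  separations.
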