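# Methods

## Model and procedure

`gopreclust` treats the expression profiles of the genes annotated to one GO
term as draws from a finite mixture of multivariate normals over the
conditions (time points or treatment interaction effects). Heterogeneity of a
class is then exactly multimodality of that mixture: if the BIC-best model
has more than one component, the class is split into its hard-assignment
subclasses, and classes with a unimodal best fit are left whole. The
resulting catalog of (sub)classes replaces the original term columns of the
membership matrix; each entry is summarized by the mean profile of its
members, the profile matrix is column-centered and decomposed by SVD, and
(sub)classes are ranked by the Mahalanobis distance of their first-two-PC
score to the score-cloud center.

Assumptions worth stating explicitly:

* Within a subclass, profiles are treated as Gaussian around a common mean
  profile; the covariance families (below) are all axis-aligned except VVV,
  so correlated residuals across conditions are only captured by the full
  model, which is fittable only for comfortably sized classes.
* Genes are weighted equally inside a class; a gene annotated to several
  terms contributes to each of them independently.
* Hard assignments: a gene belongs to exactly one subclass of a given term.
  Genes falling in clusters smaller than the minimum size are dropped *from
  that term only* — they keep their other annotations. This is what makes
  the count identity `total = (classes_in − split) + retained` hold.
* When a class is split, the whole-class column is removed, not kept
  alongside its subclasses; one column per (sub)class.

## Mixture fitting and model selection

Covariance families (mclust naming): EII (spherical, equal volume across
components), VII (spherical, varying volume), EEI (diagonal, equal), VVI
(diagonal, varying), VVV (full, varying) — with free-parameter counts
(k−1) + k·d + {1, k, d, k·d, k·d(d+1)/2}. Selection maximizes
BIC = 2·logL − n_params·log n (the larger-is-better convention; negate to
compare with lower-is-better formulations). Ties go to the smaller k, then
to the earlier family in the configured order, so selection is deterministic.

EM details:

* Initialization: kmeans++ centers seeded from the configured seed, hard
  initial responsibilities, 5 restarts per (family, k); the best final
  log-likelihood wins. k = 1 is closed-form and runs no restarts. Each GO
  term receives its own sub-seed derived by hashing (seed, term id), so
  results are independent of term iteration order and stable across runs.
* Convergence: relative log-likelihood change below 1e-8, cap 500
  iterations. The per-iteration log-likelihood trace is stored and is
  non-decreasing (EM monotonicity, tested).
* Regularization: covariance diagonals are floored at `reg`, by default
  1e-6 of the mean column variance of the class submatrix — a numerical
  floor for flat genes, not a prior.

Degenerate-solution screening. Mixture likelihoods are unbounded, and a
best-of-restarts policy actively finds the spurious optima, so two screens
reject a restart as singular rather than letting it win the BIC comparison:

* any component covariance with a minimum eigenvalue at the regularization
  floor (a component collapsed onto coincident points, or a full covariance
  estimated from fewer points than dimensions — e.g. n = d = 24, where the
  sample covariance is rank-deficient but its floored determinant explodes
  the likelihood);
* any MAP component with fewer than 2 members: a Gaussian component's
  variance is unidentifiable from a single observation, and near-singleton
  components let the *pooled*-variance families (EII/EEI) shrink their
  common variance without bound when d is large relative to n.

k = 1 diagonal fits are exempt from the floor screen so that a class of
bit-identical profiles (zero within-class variance) is reported unsplit
instead of erroring. Candidates are also skipped outright when k > 1 with
n < k + 1 or when n·d ≤ n_params. Within these rules mclust-style selection
behaves as expected on small classes: 24 pure-noise genes on 24 time points
stay unimodal, while phase-separated subgroups of 8 genes are found exactly.

Deviation from the historical tooling: the 2002-era reference
implementations initialized EM from model-based hierarchical agglomeration;
we use seeded kmeans++ restarts. On separated structure the two agree (a
cross-check against R's mclust on a two-blob instance is part of the test
suite), and no reported quantity depends on the initializer.

## ICC

The Intra Cluster Correlation of a gene set is the mean of the n(n−1)/2
strictly-lower-triangle entries of the Pearson correlation matrix of its
member profiles. It needs n ≥ 2 genes and d ≥ 3 conditions, and a
zero-variance (flat) member is a hard error naming the gene — a flat gene
inside a cluster signals an upstream filtering failure, and silently scoring
it 0 would bias the statistic. ICC is invariant under per-gene positive
affine rescaling. The mixture-based alternative — per-cluster generalized
variance det(Σ)^(1/d) — is exposed as `MixtureFit.volumes()` for diagnostic
use, but ICC is the default quality measure: a cluster of flat profiles near
zero can have a small volume yet shows a near-zero ICC.

## PCA and biplots

The profile matrix is decomposed with full SVD after column centering
(centering can be disabled to decompose the raw scaled cross-product
EᵀG_norm exactly). Scores are U·Λ and loadings the orthonormal columns of V
(the α = 1 biplot convention); explained-variance fractions are σ_i²/Σσ_j².
SVD sign indeterminacy is resolved by forcing the largest-magnitude element
of each loading vector positive, making plots reproducible bit-for-bit.
In biplots, loadings are rescaled into the score range for legibility and
the scale factor is printed in the legend; time-course conditions are drawn
as labeled points connected in order (the trajectory of the experiment),
treatments as arrows. Points are dark when their ICC exceeds the threshold
(default 0.2), and terms of interest can be starred; subclass points are
labeled `TERM.k` by their 1-based mixture-component index (indices may be
non-contiguous when a small cluster was dropped).

## Ranking and ROC

"Interestingness" of a (sub)class is its Mahalanobis distance from the
center of the first-two-PC score cloud, using the sample mean and sample
covariance of all scores (no robust estimator by default; the distances are
invariant under any affine map of the scores, so biplot scaling conventions
do not matter). The ROC sweep lowers the distance threshold through every
distinct distance value — ties enter at a single step — and reports
sensitivity and specificity against a reference term list; AUC is the
trapezoidal area, identical to the tie-corrected Mann–Whitney statistic.
A subclass counts as relevant when its parent term is in the reference list,
so a reference term is identified as soon as any one of its subclasses is
selected. Curve comparison reports ΔAUC and weak dominance on the merged
1−specificity grid.

## Synthetic data

The generator emulates the regime the method targets, not any particular
laboratory dataset. Sinusoid mode: gene g in subgroup with phase φ has
E[g, t] = A·sin(2π·2t/T + φ) + ε, ε ~ N(0, σ²) i.i.d. — the time course
traverses ≈ 2 full cycles, as in a multi-cycle synchronization experiment,
so phase-shifted subgroups are distinguishable while profiles remain
realistically correlated. Homogeneous classes get deterministic base phases
spread around the circle; split classes place their subgroups at configured
absolute phases (at σ = 0, subgroup mean correlations equal cos Δφ exactly,
tested). Treatment mode draws subgroup-specific condition means from
N(0, A²) over a small number of columns, emulating a gene × treatment
interaction matrix. Optional background genes are pure noise grouped into
"flat" classes; an optional multi-annotation mode places some genes in two
classes. Everything is a pure function of the seed; fixture files rewrite
byte-identically.

Defaults are the study conditions used throughout the tests and the
acceptance script: 24 conditions, 20 classes × 24 genes, five classes split
three ways at phases (0, π/2, π), amplitude 1, noise sd 0.2, seed 42. The
ranking benchmark instead uses five anti-correlated two-subgroup classes
(0, π), three homogeneous responsive classes and twelve flat classes, with
the eight responsive terms as the reference list — the configuration in
which class means cancel and preclustering has something to rescue.

What passing these benchmarks does **not** show: real annotation is
incomplete and hierarchical (the package deliberately performs no GO-DAG
propagation), real classes overlap heavily, real profile noise is
correlated across time points and across genes, and real subgroup structure
is rarely as separated as planted sinusoids. The benchmarks validate the
machinery — recovery when structure is recoverable, honest k = 1 when it is
not — rather than effect sizes on biological data.

## Numerical and design choices

* Expression input: TSV, header row of condition labels, first column gene
  ids; empty string or `NA` is missing. Missing values are resolved before
  anything else (`drop_gene` default — correlation and mixture fitting need
  complete rows; `row_mean_impute` available). Gene-id matching is exact,
  case-sensitive string equality.
* Annotation input: two/three-column TSV or GAF 2.x (`!` comments skipped;
  aspect P/F/C → namespace; gene id from the DB Object Symbol column by
  default, the DB Object ID column on request). GO ids must match
  `GO:\d{7}`. No evidence-code filtering, no DAG traversal.
* Class filter defaults: Biological Process namespace, ≥ 4 genes per term,
  ≥ 4 genes per retained subclass, k ≤ 8 — all configurable.
* Catalog serialization: one TSV row per (sub)class plus a one-row count
  table (# GO cl., # split, # new, # > min, total), where "# new" counts
  clusters formed by split classes *before* the size filter and "# > min"
  after; the identity total = (# GO cl. − # split) + (# > min) is enforced
  by construction.
* Exit codes of the CLI: 0 success, 2 input error, 3 degenerate-data error.
* Problem sizes in the shipped benchmarks (20 × 24 genes; 5-seed ranking
  average in the acceptance script, 20 seeds in the test suite) were chosen
  as the smallest instances on which the planted structure is unambiguous;
  larger instances only slow the suite without changing the verdicts.

## Known limitations

* BIC-based selection is unreliable when a class has barely more genes than
  the minimum (n ≈ 4–10) and many conditions; the guards keep such classes
  whole rather than splitting them spuriously, so very small heterogeneous
  classes can go undetected (a false negative, not a false positive).
* Soft (fractional) subclass membership is out of scope; assignments are
  hard.
* The alternative clustering engines the framework could host (hierarchical,
  k-medoids) are not shipped; `precluster_class` is the single extension
  point — any partitioner that returns gene subsets and a cluster count can
  replace the mixture selector.
* Correspondence Analysis, 3-D/interactive biplots, and formal significance
  tests for AUC differences are not implemented.
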