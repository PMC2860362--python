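# gopreclust

Summarizing a Gene Ontology (GO) class by the mean expression profile of its
member genes is a popular way to relate gene sets to experimental conditions.
It fails quietly when a class is *heterogeneous*: if the annotated genes fall
into phase-shifted or anti-correlated subgroups, their profiles cancel in the
mean and the class drifts to the uninformative center of any downstream
ordination — exactly the classes one would most like to see (cell-wall genes
in a synchronized cell cycle, skeletal-development genes under osteogenic
treatments) can look flat.

`gopreclust` addresses this by **preclustering**: model-based clustering of
the expression profiles *within* each GO class, before any summarization.
Heterogeneous classes are replaced by expression-homogeneous subclasses, and
only then are mean profiles formed, decomposed by PCA, and ranked.

## Method

Given an expression matrix **E** (genes × conditions; time points or
treatment interaction effects) and a binary membership matrix **G**
(genes × GO terms, terms restricted to one namespace and to ≥ 4 annotated
genes):

1. For each term, fit Gaussian mixtures to the member-gene profiles over a
   grid of covariance families (EII, VII, EEI, VVI, VVV — spherical/diagonal/
   full, equal or varying across components) and k = 1…8 components, and keep
   the fit with the best BIC (`2·logL − n_params·log n`, larger is better).
2. If k = 1 the class stays whole; otherwise it is split by the hard
   assignments, keeping only subclasses with ≥ 4 genes.
3. Each (sub)class *c* is summarized by its mean profile
   X[c, ·] = (1/n_c) Σ_{g∈c} E[g, ·] — equivalently EᵀG with membership
   columns scaled to sum 1.
4. X (column-centered) is decomposed by SVD, X = U Λ Vᵀ; scores U Λ and
   loadings V are drawn together in a biplot.
5. Cluster tightness is measured by the **Intra Cluster Correlation** (ICC):
   the mean of the strictly-lower-triangle entries of the member genes'
   Pearson correlation matrix. Tight subclasses (ICC above a threshold,
   default 0.2) are highlighted.
6. (Sub)classes are ranked by the Mahalanobis distance of their 2-D score to
   the center of the score cloud; given a reference list of relevant GO
   terms, the ranking is evaluated by a sensitivity/specificity sweep (ROC),
   with and without preclustering. A subclass inherits the relevance of its
   parent term.

A deterministic synthetic-data generator plants exactly this structure
(sinusoid time courses traversing two cycles with phase-shifted subgroups,
treatment-response vectors, flat noise classes) so every stage is testable
against known ground truth.

## Worked example

Generate a planted benchmark — 20 classes of 24 genes on a 24-point time
course; five classes consist of two anti-correlated subgroups (phases 0 and
π) whose class mean cancels to noise, three are homogeneous sinusoids, twelve
are flat noise — and analyze it with and without preclustering:

```sh
gopreclust simulate --seed 42 --out demo          # or a --spec TOML file
gopreclust run --expression demo/expression.tsv --annotation demo/annotation.tsv \
    --reference demo/reference.txt --mode both --seed 42 --out demo/out
```

which prints (abridged):

```
INFO membership: 480 genes × 20 GO classes (namespace=biological_process, min_genes=4)
preclustered: {'counts': {'n_classes_in': 20, 'n_split': 5, 'n_subclasses_formed': 10,
               'n_subclasses_retained': 10, 'n_total_out': 25},
               'explained_variance_pc12': 0.993, 'auc': 1.0}
unclustered:  {'counts': {'n_classes_in': 20, 'n_split': 0, ... 'n_total_out': 20},
               'explained_variance_pc12': 0.983, 'auc': 0.5625}
comparison:   {'delta_auc': 0.4375, 'dominates': True}
```

Reading the numbers: of 20 classes, exactly the 5 planted heterogeneous ones
were split (into 10 retained subclasses, so 25 = (20 − 5) + 10 classes come
out). Without preclustering the anti-correlated classes hide at the center of
the PCA scores and the Mahalanobis ranking finds the relevant terms no better
than chance-ish (AUC 0.56); after preclustering their subclasses move outward
and the ranking is perfect (AUC 1.0). The output directory holds the
catalogs, count tables, profile/score/loading tables, biplots and ROC curves
for both branches.

The same analysis is available as a library (`read_expression`,
`build_membership`, `precluster_catalog`, `combine`, `pca`, `biplot`,
`mahalanobis_rank`, `roc_curve`), including sklearn-style estimators
(`ConstrainedGaussianMixture`, `MixtureModelSelector`, `GOPreclusterer`,
`ProfilePCA`) that compose with sklearn tooling. A packaged reference list of
24 osteogenesis/differentiation GO terms
(`gopreclust.ranking.msc_reference_list()`) illustrates the reference-list
format.

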