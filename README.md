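# pathmarkers

Pathway-centric biomarker discovery for two-class transcriptomics studies.

Given a processed (log-scale) genes × samples expression matrix, a gene-set
collection (GMT) and binary class labels (CLS), `pathmarkers` summarises
each sample at the pathway level, ranks pathways by how strongly their
activity differs between the classes, and turns the top pathways into
compact patient encodings for classification and unsupervised clustering.
The motivating setting is clinical stratification from microarray cohorts —
for example separating post-infarction patients with ventricular
dysfunction (ejection fraction ≤ 40%) from those without — but any
two-class design with gene-set annotations fits.

## Method

For sample *i* and pathway *k* with measured member genes
*g* ∈ *MP<sub>k</sub>*, the **activity level** is the plain mean

&nbsp;&nbsp;&nbsp;&nbsp;*L<sub>i,k</sub>* = mean<sub>*g* ∈ *MP<sub>k</sub>* ∩ measured</sub> *x<sub>g,i</sub>*

Pathways with no measured gene at all are filtered out up front (the
≥ 1-measured-gene filter). Each retained pathway gets a **perturbation
score**, the unsigned two-sample *t*-statistic (pooled-variance Student
form by default, Welch selectable) comparing its *L* values across the two
classes; the signed *t* is kept so the direction of the change is
reported. Significance is calibrated by label permutation: one shared set
of *B* random label permutations (default *B* = 10 000) is applied to all
pathways, and

&nbsp;&nbsp;&nbsp;&nbsp;*P* = (*c* + 1) / (*B* + 1),

where *c* counts null scores at least as large as the observed one — so
*P* is floored at 1/(B+1) ≈ 1.0 × 10⁻⁴ at the default *B*. An exhaustive
mode enumerates all distinct label assignments exactly for small cohorts.

Samples are then encoded by the activity levels of the top-*k* pathways
(default *k* = 10), optionally mixed with individual gene expression
profiles, and evaluated with a leave-one-out cross-validated instance-based
scorer (a KStar-family Gaussian-kernel nearest-neighbour rule, bandwidth =
median pairwise training distance, per-fold standardisation) summarised by
the Mann–Whitney AUC. Every feature subset up to a size cap can be swept
to compare single against integrated pathway+gene biomarker panels.
Agglomerative clustering of the encoded samples (labels unused) with
Newick export and a two-group purity summary completes the picture, and a
pathway overlap graph (edges = shared genes among top pathways) supports
interpretation.

Deliberate contrast: the activity level is a plain mean, not a rank-based
single-sample enrichment score (ssGSEA/GSVA); gene-level GSEA is not
reimplemented — externally derived gene lists can be mixed in as features.

## Worked example

```sh
pathmarkers simulate --n-genes 2000 --n-per-class 16 16 --n-pathways 100 \
    --size-range 10 40 --n-planted 3 --effect-size 2.0 --n-unmeasured 2 \
    --seed 42 --out-dir study
pathmarkers score --expression study/expression.tsv --gmt study/pathways.gmt \
    --cls study/labels.cls --permutations 10000 --seed 42 --out-dir scored
```

which logs the sample-pathway accounting and writes the ranked table:

```
mapped 3200 (32x100) sample-pathway instances; 3136 (32x98) retained after
the >=1-measured-gene filter (2 pathway(s) dropped)

pathway  t_signed        score          n_defined  p_value
PW0049   -29.0567487416  29.0567487416  32         9.99900009999e-05
PW0001   -26.6124782859  26.6124782859  32         9.99900009999e-05
PW0084   -20.6850514676  20.6850514676  32         9.99900009999e-05
```

The three top-ranked pathways are exactly the three planted ones
(`study/truth.tsv`), each at the smallest attainable *P* = 1/(10000+1).
Encoding, classification and clustering continue from there:

```sh
pathmarkers encode --score-dir scored --top-k 10 --out encoded.tsv
pathmarkers classify --score-dir scored --cls study/labels.cls \
    --features PW0049,PW0001 --max-combo 2 --out-dir clf
pathmarkers cluster --encoded encoded.tsv --cls study/labels.cls --out-dir clu
```

```
encoded 32 samples x 10 top pathways -> encoded.tsv
evaluated 3 feature subsets; best: PW0001 (AUC=1.000)
two-group cut: cluster of 16 (VDpos=16; majority 16); cluster of 16 (VDneg=16; majority 16)
```

With a 2-SD planted effect the single-pathway LOOCV AUC saturates at 1.0
and the unsupervised two-group cut recovers the classes perfectly; real
cohorts sit well below that (see `docs/methods.md` for what the synthetic
data does and does not emulate).

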