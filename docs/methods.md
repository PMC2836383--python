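# Methods

## Model and procedure

The pipeline treats a pathway as a set of gene symbols and a sample as a
vector of processed log-scale expression values. Four stages:

1. **Activity.** For sample *i* and pathway *k*, the activity level is the
   arithmetic mean of the expression values of the pathway's member genes
   that are measured for that sample (present as a matrix row and
   non-missing). Pathways whose gene set shares no measured gene with the
   matrix are removed before scoring; the accounting (samples × total
   sets mapped, samples × retained sets kept) is logged. No variance
   standardisation of genes is applied before averaging, and genes
   belonging to several pathways contribute independently to each — shared
   genes are treated as inter-pathway links (the overlap graph), not
   partitioned.
2. **Perturbation.** Each pathway's score is the unsigned two-sample
   *t*-statistic on its activity levels across the two classes.
   Pooled-variance Student *t* is the default because it is the classical
   unqualified "*t*-statistic"; Welch is a config switch. The signed *t*
   is retained (sign convention: lexicographically smaller class label
   minus the other) so increased vs reduced expression can be partitioned.
3. **Calibration.** Class labels are permuted *B* times (default 10 000);
   the same permutation set is applied to all pathways, which preserves
   cross-pathway comparability and is *B*-fold cheaper than independent
   streams, while counting remains per-pathway. The p-value uses add-one
   smoothing, (c+1)/(B+1), avoiding p = 0 and flooring at
   1/(B+1) ≈ 1.0 × 10⁻⁴ at the default *B*. Exhaustive mode enumerates
   all C(n, n_A) distinct assignments (observed included in numerator and
   denominator) and is guarded above 20 samples.
4. **Downstream.** Samples are encoded by top-ranked pathway activities
   (default top 10) and/or raw gene rows; a leave-one-out cross-validated
   instance-based scorer and the Mann–Whitney AUC evaluate single and
   combined feature panels; average-linkage agglomerative clustering on the
   (z-scored) encodings summarises unsupervised class recovery.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| permutations *B* | 10 000 | count | p floor 1/(B+1) ≈ 1e-4; smaller B coarsens p resolution |
| t variant | pooled | pooled / welch | classical form; Welch for unequal variances |
| top_k encoding | 10 | pathways | compact patient representation by the strongest signals |
| kernel bandwidth | median pairwise training distance | feature-space distance | parameter-free, scale-adaptive |
| per-fold standardisation | on | — | activity levels and raw gene expression live on different scales when mixed |
| cluster distance / linkage | euclidean / average | — | unstated upstream; common defaults, both configurable |
| cluster feature z-scoring | on | — | large-mean pathways would otherwise dominate the metric |
| gene matching | uppercase exact | — | gene-set symbols are conventionally uppercase, platform row ids vary; `match_case` disables |
| probe collapsing | mean | mean / max | multiple rows per symbol are collapsed before pathway math |

## Numerical and degenerate-case choices

- Zero pooled variance with zero mean difference scores t = 0; zero
  variance with a non-zero difference scores ±∞, and +∞ unsigned scores
  rank above every finite score, with p computed by the same ≥ counting
  (ties count).
- Columns with fewer than two defined activity values in either class are
  unscorable: flagged NaN and excluded from the ranking with a warning.
- Ranking ties break by ascending p, then lexicographic pathway name, so
  output order is fully deterministic.
- A (sample, pathway) cell whose measured-gene count is zero while the
  pathway is measured elsewhere is undefined (NaN) and excluded from the
  t-statistic for that pathway — the filter itself acts at the pathway
  level only; per-sample gaps are this implementation's missing-data
  extension.
- The LOOCV scorer normalises kernel mass per class
  (mean-of-weights ratio), so an uninformative feature set scores every
  sample exactly 0.5 instead of drifting with the fold-wise class prior.
- All tables are written at 12 significant digits; write→read round-trips
  reproduce values to 1e-9 and byte-identical reruns are guaranteed at a
  fixed seed.

## The instance-based scorer

The reference learner in this family (KStar) defines similarity through an
entropic transform whose continuous-attribute behaviour reduces to
exponential-kernel weighting; its exact parameterisation is
under-documented for faithful reimplementation. The contract here is
therefore "instance-based probabilistic scorer under LOOCV": the default
is a Gaussian-kernel distance-weighted nearest-neighbour rule over
per-fold-standardised features, bandwidth set to the median pairwise
training distance. The scorer is a config entry so a faithful KStar can be
slotted in without touching the evaluation loop. No hyperparameter search
is performed.

## What the synthetic data emulates — and what it does not

`simulate_dataset` draws per-gene baselines μ_g ~ N(7, 1) (log-intensity
scale) and adds i.i.d. Gaussian noise (σ = 1 by default); genes of planted
pathways get a constant shift +δ in class A. Defaults reproduce the
reference study's shape: 32 samples (16 per class), 639 gene sets of which
2 contain no measured gene (leaving 637 scorable), set sizes 10–100, 10%
cross-set gene sharing, 25 000 genes. Randomness flows from a single seed
through separate sub-streams for membership, baselines and noise, so
changing the sample count does not perturb pathway membership.

It does **not** emulate gene–gene correlation within or between pathways,
platform artifacts, heavy-tailed noise, or class-dependent variance.
Passing calibration and recovery tests on this generator shows the
statistics behave correctly under their own assumptions (independent
Gaussian noise, additive gene-level effects); it does not certify
performance on real cohorts, where correlated genes inflate the variance
of pathway means and make permutation calibration the only safeguard.

Property-suite dimensions were fixed at 200 pathways × 4 000 genes with 20
replicate seeds, which gives stable Monte-Carlo estimates (± ~0.005 on the
null rejection fraction) at a few seconds per suite.

## Known limitations

- Real-data headline numbers from the motivating cohort (specific AUCs,
  14-of-16 cluster purities, the 0–4.70 score range) depend on that
  cohort, a specific historical gene-set release, and the original Weka
  learner; they are out of scope and not asserted anywhere.
- No multiple-testing adjustment is applied to pathway p-values — raw
  permutation p is the method's output; FDR control is the caller's
  decision.
- The exhaustive permutation mode is combinatorially guarded (> 20 samples
  refused by default).
- GSEA-style rank-based enrichment is intentionally absent; external gene
  lists integrate only as extra features.
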