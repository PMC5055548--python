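# Methods

## Problem and approach

Pseudoprogression (PsP) is a treatment-related imaging change in
glioblastoma patients that mimics true tumor progression (TTP) on
follow-up MRI.  On diffusion-tensor fractional-anisotropy (FA) maps the
two differ subtly: treatment-affected tissue tends to have lower FA than
recurrent tumor.  `pseudoprog` classifies subjects from longitudinal FA
maps **without segmenting the lesion**: the classifier never receives a
region of interest, only registered 2D+t image stacks and a class label
per training subject.

The pipeline has five stages:

1. **Spatio-temporal patches.**  Each subject's H×W×T FA stack is cut
   into s×s windows followed through T timepoints and vectorized to
   length m = s²·T (timepoint-major, then row-major; the order is part of
   the on-disk contract).  Each patch y is centered and scaled to the
   unit sphere, (y − ȳ)/‖y − ȳ‖₂; near-flat patches (centered norm below
   `min_contrast`, default 1e-6) are discarded.  Normalization makes
   codes invariant to affine intensity changes, so the classifier reads
   *contrast structure*, not absolute FA.
2. **Structured dictionary learning.**  Three unit-norm atom blocks are
   learned from the training patches: PsP-specific D⁽ᵖ⁾ (Kp atoms),
   TTP-specific D⁽ᵗ⁾ (Kt), and shared D⁽ˢ⁾ (Ks).  The objective sums,
   over each class's patches, the full-dictionary and permitted
   sub-dictionary squared reconstruction errors (which coincide under the
   structural constraint below) plus an incoherence penalty
   η·Σ_{blocks i≠j} ‖Dᵢᵀ Dⱼ‖²_F.  A PsP patch may only load on
   D⁽ᵖ⁾ ∪ D⁽ˢ⁾ — its D⁽ᵗ⁾ coefficients are exact zeros — and symmetrically
   for TTP.  This hard constraint, rather than a soft penalty, is what
   makes the specific blocks class-discriminative while the shared block
   absorbs anatomy common to both classes.
3. **Dual sparse encoding.**  Every patch (train or test; encoding is
   label-free) is encoded twice by orthogonal matching pursuit: over
   D⁽ᵖˢ⁾ = [D⁽ᵖ⁾, D⁽ˢ⁾] and over D⁽ᵗˢ⁾ = [D⁽ᵗ⁾, D⁽ˢ⁾], stopping at k
   nonzeros or residual ≤ σ.  The two specific-block coefficient vectors
   are stacked and the shared-block coefficients are discarded, giving a
   (Kp+Kt)-row discriminative code per patch.
4. **Pooling and DX selection.**  A subject's codes are pooled per atom
   row into one histogram (default: max of absolute coefficients;
   sqrt/mean/sum/combined also implemented).  Features are ranked by the
   DX separability score (m₁−m₀)²/(d₁²+d₀²) and the smallest top-ranked
   prefix maximizing stratified tenfold CV accuracy is selected.
5. **Classification.**  RBF-kernel SVM with per-fold inner 5-fold grid
   search over C ∈ {2⁻⁵..2¹⁵}, γ ∈ {2⁻¹⁵..2³} (powers of two, step two;
   ties toward smaller C then smaller γ), features z-scored with
   training-split statistics and class-balanced hinge weights (the
   cohorts are imbalanced and an unweighted loss biases the decision
   threshold toward the majority class).  The outer evaluation is repeated
   stratified tenfold CV; accuracy, sensitivity and specificity come from
   pooled fold predictions per repeat, AUC from pooled decision scores,
   averaged across repeats.

### Evaluation modes

`nested` (default) re-learns dictionaries and re-ranks/re-selects
features inside every outer training fold, so test subjects never
influence atoms, ranking, or hyperparameters.  `paper_faithful` learns
dictionaries once on all subjects and selects features on all subjects
before CV — the historical protocol this pipeline re-implements; it is
optimistically biased and provided for comparison only.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| s, stride, t | 13, 6 (pipeline), 3 | patch side (px), stride (px), timepoints |
| Kp, Kt, Ks | 100, 100, 10 | specific/shared dictionary sizes (atoms) |
| k (`sparsity_k`) | 10 | nonzeros per sparse code |
| η | 0.15 | incoherence weight |
| σ | e⁻⁶ ≈ 2.5e-3 | OMP residual stop (1e-6 reading available via config) |
| λ₁ | 0.05 | L1 weight of the optional LARS coding path |
| max_iters / rel_tol | 30 / 1e-4 | alternating-optimization stopping rule |
| pooling | max | histogram pooling over a subject's patches |
| CV | 10 folds × 10 repeats | outer evaluation (3 repeats in the phantom study) |

The `PatchConfig` primitive defaults to non-overlapping tiling
(stride = s); the *pipeline* default is stride 6 (≈ half-overlap).  The
overlap matters: pooled per-atom maxima are only robust to the lesion's
position relative to the patch grid when the grid samples overlapping
windows.  With non-overlapping tiles, each subject's lesion boundary
lands at a different grid phase and per-atom features do not transfer
across subjects.

## Numerical choices

* **OMP** is the orthogonal variant (full least-squares refit on the
  selected support each step, Gram-matrix recursion, batch over columns);
  atom-selection ties break to the lowest index; residual norms are
  non-increasing per step by construction.
* **Atom updates** are block-sequential (D⁽ᵖ⁾, D⁽ᵗ⁾, D⁽ˢ⁾; atoms in index
  order, one pass per outer iteration).  Each used atom solves
  (‖β‖² I + η G_other) d = E βᵀ through the Woodbury identity (G_other is
  a low-rank Gram) and is renormalized.  Because renormalization breaks
  the exact-descent property of the unconstrained solution, an update is
  *accepted only if it does not increase the monitored objective*; the
  recorded objective trace is therefore non-increasing by construction.
  Likewise the coding step keeps a column's previous code when it fits
  the current dictionary better than the fresh greedy code.
* **Unused atoms** (no nonzero coefficient among permitted samples) are
  replaced by the currently worst-reconstructed permitted patch (ties to
  the lowest column index).  Iterations containing replacements may
  increase the objective and are flagged in the training trace.
* **Degenerate DX denominators**: d₁ = d₀ = 0 with distinct means maps to
  +inf (ranked first); with equal means to 0.  Standard deviations use
  the unbiased (n−1) form.  DX ties break to the lower feature index.
* **Max pooling uses magnitudes** (|β|): OMP coefficients are signed and
  a large negative loading is as strong a contribution as a positive one;
  the mean/sum poolings are defined on absolute values for the same
  reason.
* The **selection accuracy curve** uses a fixed mid-grid SVM (C = 1,
  γ = 'scale') — the curve compares feature sets, not hyperparameters;
  the final per-fold model is then grid-searched on the selected set.
* `PipelineConfig.normalize_histograms` (off by default) L2-normalizes
  each subject's pooled histogram before classification.  It removes
  per-subject global coefficient scale — useful when training subjects'
  in-sample encoding inflates their histograms relative to held-out
  subjects — but on the phantom the histogram magnitude itself carries
  class information, so normalization costs discrimination there.
* All randomness flows from integer seeds through named
  `numpy.random.SeedSequence` streams (cohort → per-subject, learning
  init, fold assignment); every stage is a deterministic function of
  (config, seed), which the run manifest's content hashes make checkable.

## The phantom generator

Real PsP/TTP cohorts are small and private, so the package ships a
synthetic 2D+t FA phantom that emulates exactly the property the method
exploits and nothing more:

* background at FA 0.50 (archetypal deep white matter) with a smooth
  low-frequency texture (sd 0.02, ~8 px correlation cells), identical in
  law across classes;
* a disk lesion (radius 16 px on a 91×91 grid, center jittered ±2 px)
  whose mean FA is 0.25 for PsP and 0.40 for TTP — treatment effect
  disrupts microstructure more than recurrent tumor, so the PsP lesion is
  a strong FA depression and the TTP lesion a mild one; the shared
  texture rides on lesion and background alike;
* per-timepoint global drift (sd 0.01) and i.i.d. voxel noise (sd 0.03),
  clipped to [0, 1] last.

The default cohort is 15 PsP / 25 TTP.  Because patches are normalized,
the class signal reaching the classifier is the *contrast ratio* of the
lesion edge to texture-plus-noise clutter within boundary-crossing
patches — not absolute FA.  Lesion geometry is deliberately a jittered
disk, not a realistic tumor: the method never segments, so only a
localized class-dependent FA shift is required.

What the phantom does **not** emulate: anatomical structure, registration
error, eddy/motion artifacts, tensor-fit noise properties, lesion shape
heterogeneity, or longitudinal lesion evolution (lesion FA is constant
across the three timepoints).  A pass on phantoms therefore demonstrates
that the pipeline recovers a localized FA-contrast difference under
noise, drift and shared texture — it does not certify clinical
performance.

### Problem sizes used in the shipped study

The phantom study (tests and `scripts/acceptance.py`) runs the nested
protocol with Kp = Kt = 50, Ks = 5, three CV repeats, and caps the patch
columns entering dictionary learning at 3000 per fold (seeded,
class-proportional subsample; encoding always sees every patch).  These
sizes keep a full nested study at roughly five minutes on one CPU; at
full defaults the pipeline behaves identically but slower.  Dictionary
sizes near 100 and patch side 13 were the sweet spot reported for the
clinical-scale problem; on the 91×91 phantom the smaller dictionary loses
nothing measurable.

## Known limitations

* Per-patch residual ordering (a PsP patch reconstructing better under
  [D⁽ᵖ⁾, D⁽ˢ⁾] than [D⁽ᵗ⁾, D⁽ˢ⁾]) holds strongly on the patches the
  dictionary was trained on (≈90% of lesion patches) but degrades to
  little better than chance on held-out patches: a held-out lesion patch
  is dominated by class-shared clutter and both compound dictionaries
  reconstruct it to near-identical residual with k = 10 atoms.  The class
  signal survives *in aggregate* — pooled histograms classify held-out
  subjects at ≈0.95 accuracy — but the per-patch ordering is not a
  reliable held-out property on this phantom.
* `paper_faithful` mode reproduces a protocol in which dictionaries and
  feature selection see all subjects before cross-validation; its
  estimates are optimistic and should not be quoted as generalization
  performance.
* The L1/LARS coding path is provided for fidelity to the printed
  objective but is not the default and its objective trace is not
  guaranteed monotone (the descent guard is defined for the OMP path).
* Real-data mode consumes registered FA maps with a per-subject axial
  slice index; registration, FA computation and slice selection are
  upstream of this package.
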