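# pseudoprog

Segmentation-free discrimination of **pseudoprogression (PsP)** from
**true tumor progression (TTP)** in longitudinal diffusion-tensor
fractional-anisotropy (FA) maps.

After chemoradiotherapy, glioblastoma patients often show imaging changes
that mimic tumor regrowth but later stabilize (pseudoprogression).
Distinguishing the two early matters clinically, and treatment-affected
tissue tends to show *lower* FA than recurrent tumor.  `pseudoprog`
implements a classifier that exploits this without ever segmenting the
lesion: registered 2D+t FA stacks are cut into normalized spatio-temporal
patches; PsP-specific, TTP-specific and shared atom dictionaries
(D⁽ᵖ⁾, D⁽ᵗ⁾, D⁽ˢ⁾) are learned jointly under a cross-block incoherence
penalty η·Σ_{i≠j}‖DᵢᵀDⱼ‖²_F with class-structured sparse codes; every
patch is then encoded twice by orthogonal matching pursuit — over
[D⁽ᵖ⁾, D⁽ˢ⁾] and over [D⁽ᵗ⁾, D⁽ˢ⁾] — and the shared-block coefficients
are discarded.  Per-subject max-pooled coefficient histograms are ranked
by the DX separability score, DX = (m₁−m₀)²/(d₁²+d₀²), and an RBF-kernel
SVM is evaluated by repeated stratified tenfold cross-validation.  A
built-in FA phantom cohort (disk lesions with class-dependent FA on a
shared textured background) makes the whole pipeline runnable and
testable without patient data.

See `docs/methods.md` for the model, its assumptions, and what the
phantom does and does not emulate.

## Worked example

```python
import pseudoprog as pp

model = pp.PseudoprogressionModel.from_phantom(
    pp.PipelineConfig(
        learn=pp.LearnConfig(Kp=50, Kt=50, Ks=5),
        cv=pp.CVConfig(n_repeats=3),
    )
)
results = model.fit(seed=1)
print(results.summary())
```

prints

```
      Pseudoprogression vs. true progression classification
==================================================================
Subjects:            40  (PsP 15 / TTP 25)
Selection mode:      nested
Pooling:             max
Dictionary (Kp/Kt/Ks): 50/50/5
CV:                  3 x 10-fold (stratified)
------------------------------------------------------------------
Mean accuracy:       0.950  (sd 0.020)
Mean AUC:            0.954  (sd 0.050)
Sensitivity (PsP):   0.867
Specificity (TTP):   1.000
Pooled confusion:    TP=39 FP=0 FN=6 TN=75
==================================================================
```

Mean accuracy/AUC average three repeats of stratified tenfold CV in
*nested* mode: dictionaries are re-learned and features re-selected
inside every training fold, so the numbers estimate held-out-subject
performance.  Sensitivity is the recall of PsP (the positive class) on
pooled fold predictions; the confusion counts pool all three repeats.
With the class contrast removed (equal lesion FA in both classes) the
same pipeline drops to chance — see the acceptance checks below.

For real cohorts, `PseudoprogressionModel.from_manifest("manifest.tsv")`
reads registered NIfTI FA maps (tab-separated manifest: `subject_id`,
`label`, `slice_index`, semicolon-joined per-timepoint `paths`).

A thin CLI wraps the same pipeline:

```bash
pseudoprog simulate --seed 1 --out cohort/          # write a phantom cohort
pseudoprog run --seed 1 --out results/              # end-to-end + JSON summary
```

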