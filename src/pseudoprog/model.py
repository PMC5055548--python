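"""Model/Results facade over the pipeline.

``PseudoprogressionModel`` binds a labeled cohort to a pipeline
configuration; ``fit()`` runs dictionary learning, dual encoding, pooling,
DX selection and repeated SVM cross-validation and returns a
``PseudoprogressionResults`` carrying the estimates (accuracy, AUC,
sensitivity, specificity), their across-repeat dispersion, the provenance
manifest and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import CVResult
from .phantom import LabeledCohort, PhantomConfig, generate_cohort
from .pipeline import PipelineConfig, RunManifest, load_real_cohort, run_end_to_end


class PseudoprogressionModel:
    """Discriminative dictionary-learning classifier for a labeled cohort
    of longitudinal FA stacks."""

    def __init__(self, cohort: LabeledCohort | None, config: PipelineConfig | None = None):
        self.cohort = cohort
        self.config = config or PipelineConfig()

    @classmethod
    def from_phantom(cls, config: PipelineConfig | None = None, phantom: PhantomConfig | None = None):
        """Build the model on a synthetic phantom cohort.

        The cohort is generated lazily at ``fit`` time so that ``fit(seed=...)``
        reseeds cohort generation along with every other stage.
        """
        config = config or PipelineConfig()
        if phantom is not None:
            config = config.replace(phantom=phantom)
        return cls(cohort=None, config=config)

    @classmethod
    def from_manifest(cls, manifest_path, config: PipelineConfig | None = None, crop=None):
        """Build the model on a real cohort of registered NIfTI FA maps."""
        return cls(load_real_cohort(manifest_path, crop=crop), config)

    def fit(self, seed: int | None = None) -> "PseudoprogressionResults":
        if self.cohort is None:
            effective = self.config.reseeded(seed) if seed is not None else self.config
            self.cohort = generate_cohort(effective.phantom)
        result, manifest = run_end_to_end(self.config, cohort=self.cohort, seed=seed)
        return PseudoprogressionResults(self, result, manifest)


@dataclass
class PseudoprogressionResults:
    """Fitted-pipeline results: repeated-CV performance plus provenance."""

    model: PseudoprogressionModel
    cv_result: CVResult
    manifest: RunManifest

    @property
    def mean_accuracy(self) -> float:
        return self.cv_result.mean_accuracy

    @property
    def mean_auc(self) -> float:
        return self.cv_result.mean_auc

    @property
    def sensitivity(self) -> float:
        return self.cv_result.sensitivity

    @property
    def specificity(self) -> float:
        return self.cv_result.specificity

    def summary(self) -> str:
        r = self.cv_result
        labels = np.asarray(self.model.cohort.labels)
        n_psp = int((labels == "PsP").sum())
        n_ttp = len(labels) - n_psp
        cfg = self.model.config
        lines = [
            "      Pseudoprogression vs. true progression classification",
            "=" * 66,
            f"Subjects:            {len(labels)}  (PsP {n_psp} / TTP {n_ttp})",
            f"Selection mode:      {cfg.selection_mode}",
            f"Pooling:             {cfg.pooling}",
            f"Dictionary (Kp/Kt/Ks): {cfg.learn.Kp}/{cfg.learn.Kt}/{cfg.learn.Ks}",
            f"CV:                  {cfg.cv.n_repeats} x {cfg.cv.n_folds}-fold (stratified)",
            "-" * 66,
            f"Mean accuracy:       {r.mean_accuracy:.3f}  (sd {r.accuracy_per_repeat.std(ddof=0):.3f})",
            f"Mean AUC:            {r.mean_auc:.3f}  (sd {r.auc_per_repeat.std(ddof=0):.3f})",
            f"Sensitivity (PsP):   {r.sensitivity:.3f}",
            f"Specificity (TTP):   {r.specificity:.3f}",
            f"Pooled confusion:    TP={r.confusion['TP']} FP={r.confusion['FP']} "
            f"FN={r.confusion['FN']} TN={r.confusion['TN']}",
            "=" * 66,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        r = self.cv_result
        return {
            "mean_accuracy": r.mean_accuracy,
            "mean_auc": r.mean_auc,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "accuracy_per_repeat": r.accuracy_per_repeat.tolist(),
            "auc_per_repeat": r.auc_per_repeat.tolist(),
            "confusion": r.confusion,
            "mode": self.manifest.mode,
        }
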