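"""Model/Results interface tying the pipeline together.

:class:`PointSupervisedDetector` is constructed from a dataset manifest plus
configuration; ``fit()`` runs stratified fivefold cross-validation and
returns a :class:`CrossValidationResults` carrying the per-fold histories,
best checkpoints and a ``summary()`` table.  Prediction on new images goes
through the bagged TTA ensemble of the fold models.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .detector import DetectorModel, ModelConfig, load_checkpoint
from .ensemble import EnsembleOutput, TTAConfig, ensemble_predict, render_overlay
from .evalstats import EvalReport, ScoredCohort, evaluate_cohort
from .masks import MaskConfig
from .phantom import DatasetManifest, load_manifest
from .records import ImageRecord
from .training import FoldResult, TrainConfig, _load_all, run_cross_validation

__all__ = ["PointSupervisedDetector", "CrossValidationResults"]


class PointSupervisedDetector:
    """A point-supervised multiscale saliency detector bound to a dataset."""

    def __init__(
        self,
        manifest: DatasetManifest,
        model_config: Optional[ModelConfig] = None,
        train_config: Optional[TrainConfig] = None,
        mask_config: Optional[MaskConfig] = None,
        tta: Optional[TTAConfig] = None,
    ):
        self.manifest = manifest
        self.model_config = model_config or ModelConfig(backbone="tiny_fpn", input_size=256)
        self.train_config = train_config or TrainConfig()
        self.mask_config = mask_config or MaskConfig.for_input_size(self.model_config.input_size)
        self.tta = tta or TTAConfig.default()

    @classmethod
    def from_directory(cls, path, **kwargs) -> "PointSupervisedDetector":
        """Build from a generated dataset directory (annotations.jsonl)."""
        return cls(load_manifest(path), **kwargs)

    def fit(self, workdir=None) -> "CrossValidationResults":
        """Run stratified k-fold training with best-epoch selection."""
        if workdir is None:
            workdir = tempfile.mkdtemp(prefix="pelvisal_cv_")
        fold_results = run_cross_validation(
            self.manifest, self.model_config, self.train_config, self.mask_config, workdir=workdir
        )
        return CrossValidationResults(self, fold_results, workdir)


class CrossValidationResults:
    """Fitted fold models, their validation trajectories and the ensemble."""

    def __init__(self, parent: PointSupervisedDetector, fold_results: List[FoldResult], workdir):
        self.parent = parent
        self.fold_results = fold_results
        self.workdir = str(workdir)
        self.models: List[DetectorModel] = [
            load_checkpoint(r.checkpoint_path) for r in fold_results
        ]

    @classmethod
    def from_checkpoints(cls, parent: PointSupervisedDetector, paths) -> "CrossValidationResults":
        results = [
            FoldResult(
                fold_index=i, best_epoch=-1, best_validation_auroc=float("nan"),
                checkpoint_path=str(p),
            )
            for i, p in enumerate(paths)
        ]
        return cls(parent, results, Path(paths[0]).parent)

    # -- reporting --------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fold": r.fold_index,
                    "best_epoch": r.best_epoch,
                    "val_auroc": r.best_validation_auroc,
                }
                for r in self.fold_results
            ]
        )

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            "Point-supervised multiscale saliency detector",
            f"backbone: {self.parent.model_config.backbone}  "
            f"input: {self.parent.model_config.input_size}px  "
            f"folds: {len(self.fold_results)}",
            "",
            df.to_string(index=False),
            "",
            f"mean validation AUROC: {df['val_auroc'].mean():.4f}",
        ]
        return "\n".join(lines)

    # -- inference --------------------------------------------------------
    def predict(self, image) -> EnsembleOutput:
        """Bagged TTA ensemble prediction for one preprocessed image."""
        return ensemble_predict(self.models, image, self.parent.tta)

    def score_manifest(self, manifest: DatasetManifest) -> Tuple[List[str], ScoredCohort]:
        """Ensemble probability for every image of a manifest."""
        data = _load_all(manifest, self.parent.model_config.input_size)
        ids = [rec.path for rec in manifest.records]
        scores, labels, cats = [], [], []
        for img, ann in data:
            scores.append(self.predict(img).probability)
            labels.append(int(ann.is_positive))
            cats.append(list(ann.categories or []))
        return ids, ScoredCohort(scores=scores, labels=labels, categories=cats)

    def evaluate(
        self, manifest: DatasetManifest, cutoff: Optional[float] = None,
        n_boot: int = 2000, seed: int = 0,
    ) -> EvalReport:
        _, cohort = self.score_manifest(manifest)
        return evaluate_cohort(cohort, cutoff=cutoff, n_boot=n_boot, seed=seed)

    def plot_overlay(self, image: ImageRecord, out_path):
        """Render the fused localization map over the image as a PNG."""
        out = self.predict(image)
        return render_overlay(image, out.fused_map, out_path)
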