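"""Training: the multiscale pixel-wise BCE objective, fivefold
cross-validation with best-epoch selection, and the annotation-size ablation.

The objective sums, over the K pyramid levels, the per-level pixel-mean
binary cross-entropy between the saliency logits P_k and the binary
supervision masks M_k:

    L = sum_k (1/Omega_k) sum_ij -[ M_k log sigma(P_k) + (1-M_k) log(1-sigma(P_k)) ]

evaluated in the numerically stable logit form.  Every annotation point
contributes at every level (all-level assignment), so the masks are the
block-max reductions of the full-resolution disk mask.

Cross-validation folds are stratified by image-level label; after every
epoch the validation AUROC of the image-level probability is logged and the
maximum-AUROC epoch's parameters are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .augment import AugmentationRanges, apply_augmentation, sample_augmentation
from .detector import (
    ModelConfig,
    SaliencyPyramid,
    build_model,
    forward_saliency,
    image_probability,
    save_checkpoint,
)
from .io import read_image
from .masks import MaskConfig, SupervisionMaskPyramid, build_supervision_pyramid
from .phantom import DatasetManifest
from .preprocess import preprocess_image
from .records import ImageRecord, PointAnnotationSet

__all__ = [
    "TrainConfig",
    "FoldResult",
    "multiscale_bce_loss",
    "stratified_folds",
    "run_cross_validation",
    "train_fraction_ablation",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-5
    folds: int = 5
    seed: int = 0
    augment: AugmentationRanges = field(default_factory=AugmentationRanges)
    augment_training: bool = True
    clip_grad_norm: float = 10.0  # global-norm clipping; 0 disables

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 20, **kw) -> "TrainConfig":
        """Defaults for small CPU experiments: a larger step size suits the
        narrow backbone and the short schedule."""
        return cls(epochs=epochs, learning_rate=3e-3, seed=seed, **kw)


@dataclass
class FoldResult:
    fold_index: int
    best_epoch: int
    best_validation_auroc: float
    checkpoint_path: str
    history: List[Dict] = field(default_factory=list)


def multiscale_bce_loss(saliency, masks) -> float:
    """Eq. above in float64; accepts pyramids or bare lists of arrays."""
    logits = saliency.logits if isinstance(saliency, SaliencyPyramid) else list(saliency)
    targets = masks.masks if isinstance(masks, SupervisionMaskPyramid) else list(masks)
    if len(logits) != len(targets):
        raise ValueError("saliency and mask pyramids must have the same depth")
    total = 0.0
    for z, m in zip(logits, targets):
        z = np.asarray(z, dtype=np.float64)
        m = np.asarray(m, dtype=np.float64)
        if z.shape != m.shape:
            raise ValueError(f"level shape mismatch: {z.shape} vs {m.shape}")
        per_pixel = np.maximum(z, 0.0) - z * m + np.log1p(np.exp(-np.abs(z)))
        total += per_pixel.sum() / z.size
    return float(total)


# ---------------------------------------------------------------------------
# data plumbing

def _load_record(manifest: DatasetManifest, rec, input_size: int) -> Tuple[ImageRecord, PointAnnotationSet]:
    """Load one manifest record at the working resolution."""
    raw = read_image(manifest.image_path(rec))
    if raw.shape == (input_size, input_size):
        img = ImageRecord(pixels=raw, image_id=rec.path)
        ann = PointAnnotationSet(
            image_id=rec.path,
            points=list(rec.annotations.points),
            categories=rec.annotations.categories,
        )
    else:
        img = preprocess_image(raw, input_size, image_id=rec.path)
        ann = PointAnnotationSet(
            image_id=rec.path,
            points=img.map_raw_points(rec.annotations.points),
            categories=rec.annotations.categories,
        )
    return img, ann


def _load_all(manifest: DatasetManifest, input_size: int):
    return [_load_record(manifest, rec, input_size) for rec in manifest.records]


def stratified_folds(labels: Sequence[int], n_folds: int, rng: np.random.Generator):
    """Label-stratified disjoint folds with sizes differing by at most one."""
    labels = np.asarray(labels)
    pos = rng.permutation(np.flatnonzero(labels == 1))
    neg = rng.permutation(np.flatnonzero(labels == 0))
    folds = [[] for _ in range(n_folds)]
    for k, idx in enumerate(np.concatenate([pos, neg])):
        folds[k % n_folds].append(int(idx))
    return [sorted(f) for f in folds]


def _batch_masks(anns: List[PointAnnotationSet], mask_cfg: MaskConfig):
    """Per-level (N, 1, h, w) target stacks for a batch."""
    pyramids = [build_supervision_pyramid(a, mask_cfg) for a in anns]
    out = []
    for lvl in range(mask_cfg.pyramid_levels):
        out.append(np.stack([p.masks[lvl] for p in pyramids])[:, None].astype(np.float32))
    return out


def _train_one_model(
    data,
    train_idx,
    val_idx,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    mask_cfg: MaskConfig,
    fold: int,
    workdir: Path,
) -> FoldResult:
    init_seed = int(np.random.SeedSequence([train_cfg.seed, fold, 11]).generate_state(1)[0] % 2**31)
    model = build_model(model_cfg, seed=init_seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)
    val_labels = np.array([int(data[i][1].is_positive) for i in val_idx])
    history = []
    best = (-1.0, -1, None)  # (auroc, epoch, state)
    for epoch in range(train_cfg.epochs):
        erng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, fold, epoch]))
        order = erng.permutation(len(train_idx))
        losses = []
        for b0 in range(0, len(order), train_cfg.batch_size):
            batch = [data[train_idx[i]] for i in order[b0 : b0 + train_cfg.batch_size]]
            imgs, anns = [], []
            for img, ann in batch:
                if train_cfg.augment_training:
                    spec = sample_augmentation(train_cfg.augment, erng, input_size=model_cfg.input_size)
                    img, ann = apply_augmentation(img, ann, spec)
                imgs.append(img.pixels)
                anns.append(ann)
            x = np.stack(imgs)[:, None]
            targets = _batch_masks(anns, mask_cfg)
            out = model.forward(nn.Tensor(x, requires_grad=True))
            loss = nn.add_scalars(
                [nn.bce_with_logits(t, m) for t, m in zip(out, targets)]
            )
            opt.zero_grad()
            loss.backward()
            if train_cfg.clip_grad_norm:
                gnorm = np.sqrt(
                    sum(float((p.grad**2).sum()) for p in model.parameters() if p.grad is not None)
                )
                if gnorm > train_cfg.clip_grad_norm:
                    scale = train_cfg.clip_grad_norm / gnorm
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            losses.append(float(loss.data))
        scores = np.array(
            [
                image_probability(forward_saliency(model, data[i][0]), model_cfg.output_level)
                for i in val_idx
            ]
        )
        auroc = float(roc_auc_score(val_labels, scores))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auroc": auroc})
        if auroc > best[0]:
            best = (auroc, epoch, model.state_dict())
        logger.info("fold %d epoch %d loss %.4f val AUROC %.3f", fold, epoch, history[-1]["train_loss"], auroc)
    model.load_state_dict(best[2])
    path = Path(workdir) / f"fold_{fold}.npz"
    save_checkpoint(path, model)
    return FoldResult(
        fold_index=fold,
        best_epoch=best[1],
        best_validation_auroc=best[0],
        checkpoint_path=str(path),
        history=history,
    )


def run_cross_validation(
    manifest: DatasetManifest,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    mask_cfg: Optional[MaskConfig] = None,
    workdir=".",
) -> List[FoldResult]:
    """Stratified k-fold training with per-epoch validation AUROC logging."""
    if mask_cfg is None:
        mask_cfg = MaskConfig.for_input_size(model_cfg.input_size)
    if mask_cfg.mask_size != model_cfg.input_size:
        raise ValueError("mask_size must equal the model input_size")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if len(manifest) < train_cfg.folds:
        raise ValueError("need at least `folds` images")
    data = _load_all(manifest, model_cfg.input_size)
    labels = [int(ann.is_positive) for _, ann in data]
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 999]))
    folds = stratified_folds(labels, train_cfg.folds, rng)
    for k, val_idx in enumerate(folds):
        fold_labels = {labels[i] for i in val_idx}
        if fold_labels != {0, 1}:
            raise ValueError(
                f"validation fold {k} contains a single class; reshuffle with a "
                "stratified split (default) or supply more data"
            )
    results = []
    all_idx = set(range(len(data)))
    for k, val_idx in enumerate(folds):
        train_idx = sorted(all_idx - set(val_idx))
        results.append(
            _train_one_model(data, train_idx, val_idx, model_cfg, train_cfg, mask_cfg, k, workdir)
        )
    return results


def nested_subset_indices(n: int, fraction: float, seed: int) -> List[int]:
    """Indices of the ablation subset: a prefix of one seed-derived
    permutation, so smaller fractions are nested inside larger ones."""
    perm = np.random.default_rng(np.random.SeedSequence([seed, 424242])).permutation(n)
    return sorted(int(i) for i in perm[: int(round(fraction * n))])


def train_fraction_ablation(
    manifest: DatasetManifest,
    fractions: Sequence[float],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    eval_manifest: DatasetManifest,
    mask_cfg: Optional[MaskConfig] = None,
    workdir=".",
):
    """Train on nested subsets of the manifest and evaluate on a held-out set.

    Returns a pandas DataFrame with one row per fraction (fraction, n_train,
    auroc, auprc) plus a dict of per-fraction fold results.  Subsets are
    nested: a smaller fraction is a prefix of the larger one under the same
    seed-derived permutation, and fraction 1.0 reproduces plain
    cross-validation on the full manifest.
    """
    import pandas as pd

    from .ensemble import TTAConfig, ensemble_predict
    from .detector import load_checkpoint
    from .evalstats import ScoredCohort, auprc, auroc

    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError("fractions must lie in (0, 1]")
    workdir = Path(workdir)
    eval_data = _load_all(eval_manifest, model_cfg.input_size)
    eval_labels = [int(ann.is_positive) for _, ann in eval_data]
    rows = []
    details = {}
    for frac in sorted(fractions):
        sub_idx = nested_subset_indices(len(manifest), frac, train_cfg.seed)
        if len(sub_idx) < train_cfg.folds:
            raise ValueError(f"fraction {frac} yields {len(sub_idx)} images < folds")
        sub = DatasetManifest(
            records=[manifest.records[i] for i in sub_idx],
            seed=manifest.seed,
            positive_fraction=manifest.positive_fraction,
            root=manifest.root,
        )
        sub_dir = workdir / f"frac_{int(round(frac * 100)):03d}"
        fold_results = run_cross_validation(sub, model_cfg, train_cfg, mask_cfg, workdir=sub_dir)
        models = [load_checkpoint(r.checkpoint_path) for r in fold_results]
        tta = TTAConfig.default()
        scores = [
            ensemble_predict(models, img, tta).probability for img, _ in eval_data
        ]
        cohort = ScoredCohort(scores=scores, labels=eval_labels)
        rows.append(
            {
                "fraction": frac,
                "n_train": len(sub_idx),
                "auroc": auroc(cohort),
                "auprc": auprc(cohort),
            }
        )
        details[frac] = fold_results
    return pd.DataFrame(rows), details
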