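"""Supervised training and subject-level five-fold cross-validation.

Folds are assigned at the subject level: within each of the k rotations,
k-2 groups train, one group validates (early stopping) and one group is
held out for testing, so every subject is tested exactly once by a model
that never saw it. Fold leakage is asserted at runtime.

Training minimises pixel-wise cross-entropy plus macro soft-Dice over the
SAT/VAT classes with Adam; the checkpoint with the best validation Dice
(mean of SAT and VAT) is retained, and training stops early when that
metric fails to improve for ``patience`` consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentPolicy, augment_pair
from .io import SAT, VAT, read_labelmap, read_series, resolve_path
from .metrics import SegmentationScores, segmentation_scores, volume_agreement
from .nn.layers import Adam, segmentation_loss
from .nn.models import ArchitectureSpec, SegmentationModel, build_model, normalize_slice, predict_slice
from .volumetry import quantify_subject

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "TrainLog",
    "make_folds",
    "train_model",
    "cross_validate",
    "CrossValResult",
]


@dataclass(frozen=True)
class FoldPlan:
    """Subject-level assignment of a cohort into k cross-validation folds.

    ``groups`` maps subject_id -> group index in [0, k). In rotation f the
    test set is group f, the validation set group (f+1) mod k, and the
    remaining k-2 groups train.
    """

    k: int
    groups: dict[str, int]
    seed: int

    def role(self, subject_id: str, fold: int) -> str:
        g = self.groups[subject_id]
        if g == fold:
            return "test"
        if g == (fold + 1) % self.k:
            return "validation"
        return "train"

    def subjects(self, fold: int, role: str) -> list[str]:
        return [s for s in self.groups if self.role(s, fold) == role]

    def validate(self) -> None:
        """Assert the partition invariants; raises on any leakage."""
        if self.k < 2:
            raise ValueError("k must be >= 2")
        seen_as_test: dict[str, int] = {}
        for f in range(self.k):
            roles = {s: self.role(s, f) for s in self.groups}
            test = {s for s, r in roles.items() if r == "test"}
            val = {s for s, r in roles.items() if r == "validation"}
            train = {s for s, r in roles.items() if r == "train"}
            if (test & val) or (test & train) or (val & train):
                raise ValueError(f"fold {f}: train/validation/test subsets overlap")
            if test | val | train != set(self.groups):
                raise ValueError(f"fold {f}: subsets do not cover the cohort")
            for s in test:
                if s in seen_as_test:
                    raise ValueError(f"subject {s} is in the test set of folds "
                                     f"{seen_as_test[s]} and {f}")
                seen_as_test[s] = f
        if set(seen_as_test) != set(self.groups):
            missing = set(self.groups) - set(seen_as_test)
            raise ValueError(f"subjects never tested: {sorted(missing)}")


def make_folds(subject_ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldPlan:
    """Randomly partition subjects into k groups (deterministic for a seed)."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject_ids must be unique")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds the {len(ids)} subjects available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    groups = {ids[int(j)]: int(i % k) for i, j in enumerate(order)}
    plan = FoldPlan(k=k, groups=groups, seed=seed)
    plan.validate()
    return plan


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; every field is config-exposed."""

    learning_rate: float = 5e-3
    batch_size: int = 8
    max_epochs: int = 6
    patience: int = 2
    #: early stopping may not fire before this epoch count; guards against
    #: a temporary mid-training plateau being mistaken for convergence
    min_epochs: int = 0
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    #: inverse-frequency-style weights for {background, SAT, VAT}; VAT is
    #: upweighted because it covers only a few percent of abdominal pixels.
    #: Predictions divide the posteriors by these weights again (plug-in
    #: correction), so the decision rule stays calibrated.
    class_weights: tuple[float, float, float] | None = (0.4, 2.5, 8.0)
    #: multiply the learning rate by this factor each epoch from epoch
    #: ``lr_decay_start`` on (1.0 disables); settles the class boundary
    #: once the main learning phase is over
    lr_decay: float = 0.5
    lr_decay_start: int = 8
    #: train on random square crops of this size (None = full slices);
    #: a fully convolutional network predicts at full size regardless
    crop_size: int | None = None
    #: validate on every n-th slice of the validation subjects
    val_stride: int = 1
    augment: AugmentPolicy = field(default_factory=lambda: AugmentPolicy(enabled=False))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.patience < 0 or self.patience > self.max_epochs:
            raise ValueError("patience must lie in [0, max_epochs]")
        if not 0 <= self.min_epochs <= self.max_epochs:
            raise ValueError("min_epochs must lie in [0, max_epochs]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.val_stride < 1 or self.lr_decay_start < 0:
            raise ValueError("val_stride must be >= 1 and lr_decay_start >= 0")


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def _val_dice(model: SegmentationModel, pairs, correction=None) -> tuple[float, float, float]:
    """Pooled SAT/VAT Dice over (image, mask) pairs, plus their mean."""
    inter = {SAT: 0, VAT: 0}
    total = {SAT: 0, VAT: 0}
    for img, truth in pairs:
        pred, _ = predict_slice(model, img, class_weight_correction=correction)
        for lab in (SAT, VAT):
            inter[lab] += int(np.logical_and(pred == lab, truth == lab).sum())
            total[lab] += int((pred == lab).sum() + (truth == lab).sum())
    dices = {lab: (2 * inter[lab] / total[lab]) if total[lab] else 1.0 for lab in (SAT, VAT)}
    return dices[SAT], dices[VAT], (dices[SAT] + dices[VAT]) / 2.0


def train_model(
    train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    val_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    arch_spec: ArchitectureSpec,
    config: TrainConfig,
) -> tuple[SegmentationModel, TrainLog]:
    """Train one network on (image, mask) slice pairs.

    Images are raw slices; normalisation to [0, 1] happens here (and
    identically at prediction time). Returns the model restored to the
    best-on-validation parameters plus a per-epoch log. ``patience=0``
    runs exactly one epoch.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    model = build_model(arch_spec, init_seed=config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    size = arch_spec.input_size

    def prepare(img, mask, aug_seed=None):
        img = normalize_slice(img)
        if aug_seed is not None and config.augment.enabled:
            img, mask = augment_pair(img, mask, config.augment, aug_seed)
        c = config.crop_size
        if c is not None and img.shape[0] > c and img.shape[1] > c:
            r0 = int(rng.integers(img.shape[0] - c + 1))
            c0 = int(rng.integers(img.shape[1] - c + 1))
            img = img[r0:r0 + c, c0:c0 + c]
            mask = mask[r0:r0 + c, c0:c0 + c]
            return img.astype(np.float32), mask.astype(np.int64)
        if img.shape != (size, size):
            from skimage.transform import resize
            img = resize(img, (size, size), order=1, preserve_range=True, anti_aliasing=True)
            from .volumetry import resample_labels
            mask = resample_labels(mask, (size, size))
        return img.astype(np.float32), mask.astype(np.int64)

    log = TrainLog()
    best_state: list[np.ndarray] | None = None
    cw = np.asarray(config.class_weights, dtype=np.float32) if config.class_weights else None
    stale = 0
    for epoch in range(config.max_epochs):
        if epoch >= config.lr_decay_start:
            opt.lr *= config.lr_decay
        order = rng.permutation(len(train_pairs))
        losses = []
        for b0 in range(0, len(order), config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            prepared = [
                prepare(*train_pairs[i], aug_seed=int(rng.integers(2**31)))
                for i in idx
            ]
            x = np.stack([p[0] for p in prepared])[..., None]
            t = np.stack([p[1] for p in prepared])
            logits = model.forward(x)
            loss, dlogits = segmentation_loss(
                logits, t, ce_weight=config.ce_weight, dice_weight=config.dice_weight,
                class_weights=cw,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the input intensities"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        vp = val_pairs[::config.val_stride]
        d_sat, d_vat, d_mean = (_val_dice(model, vp, correction=cw)
                                if len(vp) else (float("nan"),) * 3)
        log.epochs.append({
            "epoch": epoch, "train_loss": float(np.mean(losses)),
            "val_dice_sat": d_sat, "val_dice_vat": d_vat, "val_dice_mean": d_mean,
        })
        improved = (not val_pairs) or d_mean > log.best_val_dice
        if improved:
            log.best_val_dice = d_mean if val_pairs else float("nan")
            log.best_epoch = epoch
            best_state = [p.value.copy() for p in model.params()]
            stale = 0
        else:
            stale += 1
        if stale >= config.patience and epoch + 1 >= config.min_epochs:
            break
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v
    return model, log


# ---------------------------------------------------------------------------
# cross-validation over an in-memory or on-disk cohort

@dataclass
class SubjectData:
    subject_id: str
    images: np.ndarray           # (n_slices, H, W) in-phase
    labels: np.ndarray           # (n_slices, H, W) in {0,1,2}
    geometry: object
    true_sat_l: float | None = None
    true_vat_l: float | None = None


def load_cohort(manifest: pd.DataFrame, manifest_path: str | Path | None = None) -> list[SubjectData]:
    """Materialise a labelled cohort from a dataset manifest."""
    subjects = []
    base = manifest_path if manifest_path is not None else "."
    for _, row in manifest.iterrows():
        series = read_series(resolve_path(base, row["image_path"]))
        labels, _ = read_labelmap(resolve_path(base, row["label_path"]))
        subjects.append(SubjectData(
            subject_id=row["subject_id"],
            images=series.in_phase,
            labels=labels,
            geometry=series.geometry,
            true_sat_l=row.get("true_sat_l"),
            true_vat_l=row.get("true_vat_l"),
        ))
    return subjects


@dataclass
class CrossValResult:
    """Pooled cross-validation outcome for one model arm."""

    arm: str
    pooled_scores: SegmentationScores
    per_fold_scores: list[SegmentationScores]
    volumes: pd.DataFrame         # per subject: predicted and true SAT/VAT liters
    sat_agreement: object
    vat_agreement: object
    logs: list[TrainLog]


def _pairs(subjects: Iterable[SubjectData]) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(s.images[z], s.labels[z]) for s in subjects for z in range(s.images.shape[0])]


def cross_validate(
    cohort: Sequence[SubjectData],
    arch_spec: ArchitectureSpec,
    config: TrainConfig,
    k: int = 5,
    fold_seed: int = 0,
    fold_plan: FoldPlan | None = None,
    arm_name: str | None = None,
) -> CrossValResult:
    """Run subject-level k-fold cross-validation for one model arm.

    Every subject's test prediction comes from the fold in which it was
    held out; pooled pixel scores and per-subject volume agreement are
    computed over the whole cohort. Raises if the fold plan leaks.
    """
    by_id = {s.subject_id: s for s in cohort}
    plan = fold_plan or make_folds(sorted(by_id), k=k, seed=fold_seed)
    plan.validate()
    if set(plan.groups) != set(by_id):
        raise ValueError("fold plan does not cover exactly the cohort subjects")

    pooled_pred: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    per_fold = []
    logs = []
    vol_rows = []
    for f in range(plan.k):
        train_ids = plan.subjects(f, "train")
        val_ids = plan.subjects(f, "validation")
        test_ids = plan.subjects(f, "test")
        assert not (set(train_ids) | set(val_ids)) & set(test_ids), "fold leakage"
        model, log = train_model(
            _pairs(by_id[s] for s in train_ids),
            _pairs(by_id[s] for s in val_ids),
            arch_spec,
            replace(config, seed=config.seed + f),
        )
        logs.append(log)
        cw = np.asarray(config.class_weights, dtype=np.float32) if config.class_weights else None
        fold_pred, fold_truth = [], []
        for sid in test_ids:
            subj = by_id[sid]
            pred_stack = np.stack([
                predict_slice(model, img, class_weight_correction=cw)[0]
                for img in subj.images
            ])
            fold_pred.append(pred_stack)
            fold_truth.append(subj.labels)
            vols = quantify_subject(pred_stack, subj.geometry)
            true = quantify_subject(subj.labels, subj.geometry)
            vol_rows.append({
                "subject_id": sid, "fold": f,
                "pred_sat_l": vols.sat_l, "pred_vat_l": vols.vat_l, "pred_tat_l": vols.tat_l,
                "true_sat_l": true.sat_l, "true_vat_l": true.vat_l, "true_tat_l": true.tat_l,
            })
        per_fold.append(segmentation_scores(np.concatenate(fold_pred).ravel(),
                                            np.concatenate(fold_truth).ravel()))
        pooled_pred.extend(fold_pred)
        pooled_truth.extend(fold_truth)

    pooled = segmentation_scores(np.concatenate([p.ravel() for p in pooled_pred]),
                                 np.concatenate([t.ravel() for t in pooled_truth]))
    volumes = pd.DataFrame(vol_rows).sort_values("subject_id").reset_index(drop=True)
    return CrossValResult(
        arm=arm_name or f"{arch_spec.name}+aug" if config.augment.enabled else f"{arch_spec.name}",
        pooled_scores=pooled,
        per_fold_scores=per_fold,
        volumes=volumes,
        sat_agreement=volume_agreement(volumes["pred_sat_l"], volumes["true_sat_l"]),
        vat_agreement=volume_agreement(volumes["pred_vat_l"], volumes["true_vat_l"]),
        logs=logs,
    )
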