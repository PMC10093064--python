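"""Inference protocol, segmentation metrics, and k-fold cross-validation.

Inference segments a whole query scan from a single annotated support slice:
a slice from the middle of the support volume's foreground extent provides
the prototype, every query slice is scored against it, and the upsampled
probabilities are binarized at 0.5. Quality is summarized per volume (pooled
over slices in 3-D) by the Dice similarity coefficient

    D(X, Y) = 2 |X n Y| / (|X| + |Y|),

intersection-over-union |X n Y| / |X u Y|, and precision TP / (TP + FP).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .encoder import encode
from .episodes import make_inference_episode
from .preprocess import SliceStack
from .prototype import (
    downsample_mask,
    masked_average_pool,
    resize_to_mask,
    similarity_map,
    soft_threshold,
)
from .training import ModelState, TrainConfig, train

__all__ = [
    "MetricsRecord",
    "select_support_slice",
    "segment_query_volume",
    "compute_metrics",
    "cross_validate",
]


@dataclass
class MetricsRecord:
    """Per-volume overlap metrics; precision is NaN when undefined (no
    predicted foreground)."""

    dice: float
    iou: float
    precision: float
    case_id: str = ""
    fold: int = -1


def select_support_slice(
    mask_volume: np.ndarray,
    mode: str = "median",
    rng: np.random.Generator | None = None,
) -> int:
    """Pick the support slice from the middle of the foreground extent.

    ``mode='median'`` deterministically returns the median foreground-bearing
    slice index; ``mode='middle-third'`` draws uniformly (seeded via ``rng``)
    from the middle third of the foreground-bearing range.
    """
    mask_volume = np.asarray(mask_volume)
    fg = np.flatnonzero(mask_volume.reshape(mask_volume.shape[0], -1).any(axis=1))
    if fg.size == 0:
        raise ValueError("support volume has no foreground-bearing slice")
    if mode == "median":
        return int(fg[fg.size // 2])
    if mode == "middle-third":
        if rng is None:
            raise ValueError("middle-third mode needs an rng")
        third = max(fg.size // 3, 1)
        mid = fg[third : fg.size - third] if fg.size >= 3 else fg
        if mid.size == 0:
            mid = fg
        return int(rng.choice(mid))
    raise ValueError(f"unknown mode {mode!r}")


def segment_query_volume(
    support_stack: SliceStack,
    support_slice: int,
    query_stack: SliceStack,
    model: ModelState,
    prob_threshold: float = 0.5,
) -> np.ndarray:
    """Segment every slice of a query stack from one support slice.

    One prototype is pooled from the support slice's foreground; each query
    slice is scored, the similarity map upsampled to mask resolution,
    soft-thresholded with the model's beta and binarized at
    ``prob_threshold``. Returns a binary (n, H, W) volume.
    """
    if not 0.0 < prob_threshold < 1.0:
        raise ValueError("prob_threshold must be in (0, 1)")
    episode = make_inference_episode(support_stack, support_slice, query_stack)
    batch = np.concatenate([episode.support_images, episode.query_images], axis=0)
    fmap = encode(batch, model.encoder, n_support=episode.n_support)
    feat_res = fmap.data.data.shape[-2:]

    small = downsample_mask(episode.support_masks[0], feat_res)
    if small.sum() == 0:
        rr, cc = np.nonzero(episode.support_masks[0])
        small = np.zeros(feat_res, dtype=np.uint8)
        small[
            min(int(round(rr.mean() / 8)), feat_res[0] - 1),
            min(int(round(cc.mean() / 8)), feat_res[1] - 1),
        ] = 1
    proto = masked_average_pool(fmap.support.data[0], small)

    mask_dims = query_stack.masks.shape[-2:]
    out = np.empty((query_stack.n_slices, *mask_dims), dtype=np.uint8)
    q_feats = fmap.query.data
    for qi in range(query_stack.n_slices):
        r = similarity_map(q_feats[qi], proto, alpha=model.alpha)
        m = soft_threshold(resize_to_mask(r, mask_dims), float(model.beta.data))
        out[qi] = (m >= prob_threshold).astype(np.uint8)
    return out


def compute_metrics(pred: np.ndarray, truth: np.ndarray, case_id: str = "", fold: int = -1) -> MetricsRecord:
    """Dice, IoU and precision between binary volumes, in integer arithmetic.

    Conventions: two empty masks give dice = iou = 1; precision is NaN when
    nothing is predicted foreground.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    p = int(np.count_nonzero(pred))
    t = int(np.count_nonzero(truth))
    union = p + t - tp
    dice = 1.0 if p + t == 0 else 2.0 * tp / (p + t)
    iou = 1.0 if union == 0 else tp / union
    precision = np.nan if p == 0 else tp / p
    return MetricsRecord(dice=dice, iou=iou, precision=precision, case_id=case_id, fold=fold)


def _fold_partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(perm[i::k]) for i in range(k)]


def cross_validate(
    dataset: list[SliceStack],
    config: TrainConfig,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> dict:
    """k-fold cross-validation: train on k-1 folds, segment each held-out case.

    Each validation case is segmented as the query, using the median
    foreground slice of a support case drawn (seeded) from the training
    folds. Returns per-case records plus mean/sd and per-fold maxima of
    dice, iou and precision.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} cases is smaller than k={k}")
    rng = np.random.default_rng(0) if rng is None else rng
    folds = _fold_partition(len(dataset), k, rng)
    records: list[MetricsRecord] = []
    for fold_idx, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(dataset)), val_idx)
        train_cases = [dataset[i] for i in train_idx]
        fold_cfg = replace(config, seed=config.seed + fold_idx)
        model, _ = train(train_cases, fold_cfg)
        for vi in val_idx:
            query = dataset[vi]
            support = train_cases[int(rng.integers(len(train_cases)))]
            s_idx = select_support_slice(support.masks)
            pred = segment_query_volume(support, s_idx, query, model)
            records.append(
                compute_metrics(
                    pred, query.masks, case_id=query.source_id, fold=fold_idx
                )
            )
    return summarize_metrics(records)


def summarize_metrics(records: list[MetricsRecord]) -> dict:
    """Aggregate per-case records into mean, sd and max for each metric."""
    out: dict = {"per_case": records}
    for name in ("dice", "iou", "precision"):
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[name] = {
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "max": float(vals.max()) if vals.size else np.nan,
        }
    return out
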