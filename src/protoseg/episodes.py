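"""Episodic sampling of support/query slices and encoder batch assembly.

An episode is the unit of both training and inference: a support set of
C*K labeled (image, mask) slice pairs and a query set to segment. Training
episodes pair a single query slice with C*K support slices drawn from the
*same* case but different slice indices, all of them containing foreground.
Inference episodes carry a whole standardized query stack.

With all tumor levels merged into one binary foreground class, "ways" do not
multiply classes; a C-shot K-way episode simply draws C*K support slices for
the single merged class. The concatenated support+query encoder batch for a
standard 21-slice query stack therefore has batch dimension C*K + 21
(22, 26, 31, 46, 71 ... for the usual shot/way settings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import STANDARD_SLICES, SliceStack

__all__ = ["Episode", "sample_training_episode", "make_inference_episode", "build_encoder_batch"]


@dataclass
class Episode:
    """Support (image, mask) pairs plus a query set.

    support_images: (C*K, 3, H, W); support_masks: (C*K, H, W), each with at
    least one foreground pixel; query_images: (nq, 3, H, W) with nq = 1 for
    training episodes and the full stack for inference episodes.
    """

    support_images: np.ndarray
    support_masks: np.ndarray
    query_images: np.ndarray
    query_masks: np.ndarray
    case_ids: tuple[str, ...] = ()
    support_slice_indices: tuple[int, ...] = ()
    query_slice_indices: tuple[int, ...] = ()

    def __post_init__(self):
        if self.support_images.shape[0] == 0:
            raise ValueError("episode needs at least one support slice")
        if self.support_images.shape[0] != self.support_masks.shape[0]:
            raise ValueError("support images and masks must be paired")
        empties = ~self.support_masks.reshape(self.support_masks.shape[0], -1).any(axis=1)
        if empties.any():
            raise ValueError("every support mask must contain foreground")

    @property
    def n_support(self) -> int:
        return self.support_images.shape[0]


def sample_training_episode(
    dataset: list[SliceStack], C: int, K: int, rng: np.random.Generator
) -> Episode:
    """Draw one training episode: 1 query slice + C*K support slices, all
    foreground-bearing, from a single randomly chosen case.

    Cases with fewer than C*K + 1 foreground-bearing slices are skipped by
    resampling; if no case qualifies, raises ValueError.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if C < 1 or K < 1:
        raise ValueError("C and K must be >= 1")
    need = C * K + 1
    order = rng.permutation(len(dataset))
    for idx in order:
        stack = dataset[idx]
        fg = stack.foreground_slices()
        if len(fg) < need:
            continue
        chosen = rng.choice(fg, size=need, replace=False)
        q, s = int(chosen[0]), chosen[1:]
        return Episode(
            support_images=stack.images[s],
            support_masks=stack.masks[s].astype(np.uint8),
            query_images=stack.images[[q]],
            query_masks=stack.masks[[q]].astype(np.uint8),
            case_ids=(stack.source_id,),
            support_slice_indices=tuple(int(i) for i in s),
            query_slice_indices=(q,),
        )
    raise ValueError(f"no case has the {need} foreground-bearing slices required")


def make_inference_episode(
    support_stack: SliceStack, support_slice: int, query_stack: SliceStack, C: int = 1, K: int = 1
) -> Episode:
    """Build an inference episode: the chosen support slice (replicated to
    C*K exemplars) against the whole query stack."""
    if not support_stack.masks[support_slice].any():
        raise ValueError(f"support slice {support_slice} has no foreground")
    reps = C * K
    return Episode(
        support_images=np.repeat(support_stack.images[[support_slice]], reps, axis=0),
        support_masks=np.repeat(
            support_stack.masks[[support_slice]].astype(np.uint8), reps, axis=0
        ),
        query_images=query_stack.images,
        query_masks=query_stack.masks.astype(np.uint8),
        case_ids=(support_stack.source_id, query_stack.source_id),
        support_slice_indices=(support_slice,) * reps,
        query_slice_indices=tuple(range(query_stack.n_slices)),
    )


def build_encoder_batch(episode: Episode, pad_query_to: int | None = None) -> np.ndarray:
    """Concatenate [support || query] along the batch axis.

    For inference episodes whose query stack is the standard slice count, the
    batch dimension is C*K + 21. ``pad_query_to`` cyclically pads a shorter
    query set up to the standard stack length when requested.
    """
    s, q = episode.support_images, episode.query_images
    if s.shape[1:] != q.shape[1:]:
        raise ValueError(f"mixed image sizes: support {s.shape[1:]} vs query {q.shape[1:]}")
    if pad_query_to is not None and q.shape[0] < pad_query_to:
        reps = np.resize(np.arange(q.shape[0]), pad_query_to)
        q = q[reps]
    return np.concatenate([s, q], axis=0)
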