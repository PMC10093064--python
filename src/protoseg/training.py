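"""Losses and the episodic end-to-end training loop.

Each iteration samples one episode, encodes support and query slices with a
shared encoder, pools the support foreground into a single prototype, scores
the query features against it, upsamples the similarity map to mask
resolution and soft-thresholds it into a dense foreground probability. Two
losses drive learning:

* a class-weighted binary cross-entropy segmentation loss (foreground weight
  1.0, background weight 0.2, mean over pixels), and
* a prototype-alignment regularization (PAR) that reverses the roles: a
  prototype pooled from the *query* features under the predicted query mask
  (binarized at 0.5) must segment the *support* slices.

The total loss is L_total = L_seg + lambda * L_PAR with lambda defaulting
to 1. Optimization is stochastic gradient descent with momentum 0.9, batch
size 1 (one episode), learning rate 1e-3 multiplied by 0.97 every 1000
iterations, and L2 weight decay 5e-4. The soft-threshold scalar beta is
trained jointly with the encoder, initialized at -alpha/2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .encoder import build_encoder, encode
from .episodes import Episode, build_encoder_batch, sample_training_episode
from .preprocess import AugmentConfig, augment
from .prototype import (
    DEFAULT_ALPHA,
    downsample_mask,
    masked_average_pool,
    resize_to_mask,
    similarity_map,
    soft_threshold,
)

__all__ = [
    "TrainConfig",
    "ModelState",
    "LossReport",
    "segmentation_loss",
    "par_loss",
    "total_loss",
    "forward_episode",
    "train",
]

_PROB_EPS = 1e-7  # probability clamp inside the cross-entropy


@dataclass
class TrainConfig:
    """Optimizer and episode settings for episodic training."""

    iterations: int = 50_000
    learning_rate: float = 1e-3
    momentum: float = 0.9
    lr_decay: float = 0.97  # multiplied in every `lr_decay_every` iterations
    lr_decay_every: int = 1000
    weight_decay: float = 5e-4
    batch_size: int = 1
    shots: int = 1  # C
    ways: int = 1  # K
    alpha: float = DEFAULT_ALPHA
    beta_init: float = -DEFAULT_ALPHA / 2.0
    lambda_par: float = 1.0
    fg_weight: float = 1.0
    bg_weight: float = 0.2
    compute_par: bool = True
    augment: bool = True
    encoder: str = "compact"
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.momentum, self.lr_decay) < 0:
            raise ValueError("rates must be positive")
        if self.lambda_par < 0:
            raise ValueError("lambda_par must be >= 0")


@dataclass
class LossReport:
    iteration: int
    l_seg: float
    l_par: float
    l_total: float
    learning_rate: float


@dataclass
class ModelState:
    """Trainable state: the encoder plus the soft-threshold scalar beta."""

    encoder: object
    beta: Tensor
    alpha: float = DEFAULT_ALPHA

    @property
    def parameters(self) -> dict[str, Tensor]:
        return {**self.encoder.params, "beta": self.beta}

    def save(self, path: str | Path) -> None:
        arrays = {k: v.data for k, v in self.parameters.items()}
        arrays["alpha"] = np.asarray(self.alpha)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path, encoder_name: str = "compact") -> "ModelState":
        enc = build_encoder(encoder_name)
        with np.load(path) as st:
            state = dict(st)
        alpha = float(state.pop("alpha"))
        beta = Tensor(float(state.pop("beta")), requires_grad=True)
        enc.load_state_dict(state)
        return cls(encoder=enc, beta=beta, alpha=alpha)


def init_model(config: TrainConfig) -> ModelState:
    enc = build_encoder(config.encoder, seed=config.seed)
    return ModelState(
        encoder=enc,
        beta=Tensor(config.beta_init, requires_grad=True),
        alpha=config.alpha,
    )


# ---- losses ----------------------------------------------------------------


def segmentation_loss(pred, truth: np.ndarray, fg_weight: float = 1.0, bg_weight: float = 0.2):
    """Class-weighted binary cross-entropy, mean over pixels.

    Foreground pixels contribute fg_weight * (-log M); background pixels
    contribute bg_weight * (-log(1 - M)). Probabilities are clamped to
    [1e-7, 1 - 1e-7] for numerical safety. Accepts a Tensor (differentiable)
    or an array for ``pred``.
    """
    m = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float64))
    truth = np.asarray(truth, dtype=np.float64)
    if m.data.shape != truth.shape:
        raise ValueError(f"prediction {m.data.shape} vs truth {truth.shape}")
    mc = m.clamp(_PROB_EPS, 1.0 - _PROB_EPS)
    per_pixel = (-fg_weight) * truth * mc.log() + (-bg_weight) * (1.0 - truth) * (
        1.0 - mc
    ).log()
    loss = per_pixel.mean()
    return loss if isinstance(pred, Tensor) else loss.item()


def total_loss(l_seg, l_par, lambda_par: float = 1.0):
    """L_total = L_seg + lambda * L_PAR."""
    return l_seg + lambda_par * l_par


def par_loss(
    query_features,
    predicted_query_mask,
    support_features,
    support_masks: np.ndarray,
    beta,
    alpha: float = DEFAULT_ALPHA,
    fg_weight: float = 1.0,
    bg_weight: float = 0.2,
):
    """Prototype-alignment regularization.

    Pools a query-derived prototype over the predicted query mask (binarized
    at 0.5, downsampled to feature resolution), scores every support feature
    grid against it, soft-thresholds, upsamples to the support mask dims and
    returns the weighted cross-entropy against the support ground truth
    (mean over pixels). If the binarized predicted mask is empty the term
    is 0 (the prototype would be undefined).

    query_features: (C, h, w); support_features: (S, C, h, w) Tensor/array.
    """
    pred = (
        predicted_query_mask.data
        if isinstance(predicted_query_mask, Tensor)
        else np.asarray(predicted_query_mask)
    )
    feat_res = query_features.data.shape[-2:] if isinstance(query_features, Tensor) else np.asarray(query_features).shape[-2:]
    hard = (pred >= 0.5).astype(np.uint8)
    hard_small = downsample_mask(hard, feat_res)
    if hard_small.sum() == 0:
        return Tensor(0.0) if isinstance(query_features, Tensor) else 0.0
    q_proto = masked_average_pool(query_features, hard_small)
    n_support = support_masks.shape[0]
    losses = []
    for s in range(n_support):
        feats = support_features[s]
        r = similarity_map(feats, q_proto, alpha=alpha)
        r_up = resize_to_mask(r, support_masks.shape[-2:])
        m = soft_threshold(r_up, beta)
        losses.append(
            segmentation_loss(m, support_masks[s], fg_weight=fg_weight, bg_weight=bg_weight)
        )
    out = losses[0]
    for l in losses[1:]:
        out = out + l
    return out / float(n_support) if isinstance(out, Tensor) else out / n_support


# ---- forward pass ----------------------------------------------------------


def forward_episode(episode: Episode, model: ModelState, config: TrainConfig):
    """Run the full differentiable pipeline on one training episode.

    Returns (l_seg, l_par, l_total, predicted_query_mask_array).
    """
    batch = build_encoder_batch(episode)
    fmap = encode(batch, model.encoder, n_support=episode.n_support)
    feat_res = fmap.data.data.shape[-2:]
    sup_feats = fmap.support
    q_feats = fmap.query

    # support prototype: average the support-slice prototypes (one per shot)
    protos = []
    for s in range(episode.n_support):
        small = downsample_mask(episode.support_masks[s], feat_res)
        if small.sum() == 0:  # tiny foreground vanished at /8; fall back to bbox center
            small = np.zeros(feat_res, dtype=np.uint8)
            rr, cc = np.nonzero(episode.support_masks[s])
            small[
                min(int(round(rr.mean() / 8)), feat_res[0] - 1),
                min(int(round(cc.mean() / 8)), feat_res[1] - 1),
            ] = 1
        protos.append(masked_average_pool(sup_feats[s], small))
    proto = protos[0]
    for p in protos[1:]:
        proto = proto + p
    proto = proto / float(len(protos))

    # score each query slice; training episodes have exactly one
    mask_dims = episode.query_masks.shape[-2:]
    seg_losses = []
    pred_masks = []
    for qi in range(episode.query_images.shape[0]):
        r = similarity_map(q_feats[qi], proto, alpha=config.alpha)
        r_up = resize_to_mask(r, mask_dims)
        m = soft_threshold(r_up, model.beta)
        pred_masks.append(m)
        seg_losses.append(
            segmentation_loss(
                m, episode.query_masks[qi], fg_weight=config.fg_weight, bg_weight=config.bg_weight
            )
        )
    l_seg = seg_losses[0]
    for l in seg_losses[1:]:
        l_seg = l_seg + l
    l_seg = l_seg / float(len(seg_losses))

    if config.compute_par:
        l_par = par_loss(
            q_feats[0],
            pred_masks[0],
            sup_feats,
            episode.support_masks,
            model.beta,
            alpha=config.alpha,
            fg_weight=config.fg_weight,
            bg_weight=config.bg_weight,
        )
    else:
        l_par = Tensor(0.0)
    l_total = total_loss(l_seg, l_par, config.lambda_par)
    return l_seg, l_par, l_total, pred_masks[0].data


def _augment_episode(episode: Episode, rng: np.random.Generator) -> Episode:
    """Random affine augmentation of every slice in the episode; a slice whose
    mask would lose all foreground keeps its original."""
    cfg = AugmentConfig()
    si, sm = augment(episode.support_images, episode.support_masks, rng, cfg)
    qi, qm = augment(episode.query_images, episode.query_masks, rng, cfg)
    for k in range(sm.shape[0]):
        if not sm[k].any():
            si[k], sm[k] = episode.support_images[k], episode.support_masks[k]
    for k in range(qm.shape[0]):
        if not qm[k].any():
            qi[k], qm[k] = episode.query_images[k], episode.query_masks[k]
    return Episode(
        support_images=si,
        support_masks=sm,
        query_images=qi,
        query_masks=qm,
        case_ids=episode.case_ids,
        support_slice_indices=episode.support_slice_indices,
        query_slice_indices=episode.query_slice_indices,
    )


# ---- optimizer and loop ----------------------------------------------------


class _SGDMomentum:
    def __init__(self, params: dict[str, Tensor], lr: float, momentum: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.velocity[k] = self.momentum * self.velocity[k] + g
            p.data = p.data - self.lr * self.velocity[k]


def train(
    dataset: list,
    config: TrainConfig,
    out_dir: str | Path | None = None,
) -> tuple[ModelState, list[LossReport]]:
    """Episodic training over preprocessed cases (SliceStacks).

    Per iteration: sample episode -> encode -> prototype -> similarity ->
    soft threshold -> weighted BCE + PAR -> SGD-momentum step, with the
    learning rate decayed by ``lr_decay`` every ``lr_decay_every`` iterations.
    Fully deterministic for a fixed config seed. Writes ``loss_history.jsonl``
    and ``checkpoint.npz`` to ``out_dir`` when given.

    Raises RuntimeError with diagnostics if the loss ever goes non-finite.
    """
    if not dataset:
        raise ValueError("training requires at least one case")
    rng = np.random.default_rng(config.seed)
    model = init_model(config)
    opt = _SGDMomentum(
        model.parameters, config.learning_rate, config.momentum, config.weight_decay
    )
    history: list[LossReport] = []
    for it in range(config.iterations):
        opt.lr = config.learning_rate * config.lr_decay ** (it // config.lr_decay_every)
        episode = sample_training_episode(dataset, config.shots, config.ways, rng)
        if config.augment:
            episode = _augment_episode(episode, rng)
        opt.zero_grad()
        l_seg, l_par, l_tot, _ = forward_episode(episode, model, config)
        if not np.isfinite(l_tot.data):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: "
                f"l_seg={l_seg.data}, l_par={l_par.data}"
            )
        l_tot.backward()
        opt.step()
        history.append(
            LossReport(
                iteration=it,
                l_seg=float(l_seg.data),
                l_par=float(l_par.data),
                l_total=float(l_tot.data),
                learning_rate=opt.lr,
            )
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "loss_history.jsonl", "w") as fh:
            for rec in history:
                fh.write(json.dumps(asdict(rec)) + "\n")
        model.save(out_dir / "checkpoint.npz")
    return model, history
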