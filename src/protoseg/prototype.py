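"""Foreground prototypes, scaled-cosine scoring and soft thresholding.

The foreground class is represented in embedding space by a single prototype
rho: the masked average of feature vectors over foreground locations. A query
feature grid is scored against the prototype with a negated, scaled cosine
(Tucker congruence) similarity

    R(i, j) = -alpha * <chi(i,j), rho> / (||chi(i,j)|| * ||rho||),

so perfectly matching pixels score -alpha and incongruent pixels score near
+alpha; alpha defaults to 20. The dense foreground probability is obtained by
soft thresholding with a sigmoid around a learnable scalar beta:

    M(i, j) = 1 - sigmoid(R(i, j) - beta),

which is exactly 0.5 where R = beta and increases as R falls below beta.

All operators accept either plain numpy arrays (returning arrays) or autodiff
Tensors (returning Tensors, so gradients flow during training).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "masked_average_pool",
    "similarity_map",
    "soft_threshold",
    "resize_to_mask",
    "downsample_mask",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 20.0
_NORM_EPS = 1e-12  # guards zero feature vectors: their cosine is defined as 0


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def masked_average_pool(features, mask: np.ndarray):
    """Prototype by masked average pooling: the mean feature vector over
    foreground locations of ``mask``.

    features: (C, H, W) grid (Tensor or array); mask: (H, W) binary array at
    feature resolution with at least one foreground location.
    Returns a (C,) prototype of the same kind as ``features``.
    """
    feats, was_tensor = _wrap(features)
    mask = np.asarray(mask)
    if mask.shape != feats.data.shape[1:]:
        raise ValueError(f"mask {mask.shape} not aligned with features {feats.data.shape[1:]}")
    count = float(mask.sum())
    if count == 0:
        raise ValueError("masked average pooling is undefined for an empty mask")
    proto = (feats * mask.astype(np.float64)).sum(axis=(1, 2)) / count
    return proto if was_tensor else proto.data


def similarity_map(features, prototype, alpha: float = DEFAULT_ALPHA):
    """Anomaly-style similarity scores R = -alpha * cosine(chi, rho).

    features: (C, H, W); prototype: (C,) nonzero. Scores lie in [-alpha,
    alpha]; the most prototype-like pixels score near -alpha. Pixels with a
    zero feature vector score 0.
    """
    feats, ft = _wrap(features)
    proto, pt = _wrap(prototype)
    pnorm = float(np.linalg.norm(proto.data))
    if pnorm == 0:
        raise ValueError("prototype must be nonzero")
    dots = (feats * proto.reshape(-1, 1, 1)).sum(axis=0)
    fnorm = ((feats * feats).sum(axis=0) + _NORM_EPS).sqrt()
    pn = (proto * proto).sum() ** 0.5
    r = (-alpha) * dots / (fnorm * pn)
    return r if (ft or pt) else r.data


def soft_threshold(scores, beta):
    """Foreground probability M = 1 - sigmoid(R - beta); M(beta) = 0.5 exactly
    and M decreases strictly as R increases."""
    r, rt = _wrap(scores)
    b, bt = _wrap(beta)
    m = 1.0 - (r - b).sigmoid()
    return m if (rt or bt) else m.data


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D linear interpolation matrix (endpoint-aligned)."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = pos - lo
    a[np.arange(n_out), lo] += 1.0 - w
    a[np.arange(n_out), hi] += w
    return a


def resize_to_mask(grid, target: tuple[int, int]):
    """Bilinear resize of a (H, W) or (C, H, W) grid to ``target`` dims.

    Endpoint-aligned separable linear interpolation, expressed as two matrix
    products so it is exactly differentiable; an identity resize returns the
    input values unchanged.
    """
    x, was_tensor = _wrap(grid)
    ty, tx = int(target[0]), int(target[1])
    if ty < 1 or tx < 1:
        raise ValueError("target dims must be positive")
    h, w = x.data.shape[-2:]
    a = Tensor(_interp_matrix(h, ty))
    bt = Tensor(_interp_matrix(w, tx).T)
    if x.ndim == 2:
        out = a @ (x @ bt)
    else:
        c = x.data.shape[0]
        flat = x.reshape(c * h, w) @ bt  # (c*h, tx)
        out = (a @ flat.reshape(c, h, tx).transpose((1, 0, 2)).reshape(h, c * tx)).reshape(
            ty, c, tx
        ).transpose((1, 0, 2))
    return out if was_tensor else out.data


def downsample_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour downsampling of a binary mask to feature resolution."""
    mask = np.asarray(mask)
    h, w = mask.shape
    rows = np.round(np.linspace(0.0, h - 1.0, target[0])).astype(int)
    cols = np.round(np.linspace(0.0, w - 1.0, target[1])).astype(int)
    return mask[np.ix_(rows, cols)]
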