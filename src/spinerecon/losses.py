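"""Training objectives.

The integrated segmentation objective is a weighted sum of four terms,

    L = lambda * L_Dice + alpha_w * L_Hausdorff + beta * L_Focal
        + gamma_adv * L_GAN(G),

with defaults (10, 1e-4, 10, 0.1).  The Hausdorff term is the distance-
transform surrogate: the mean over the voxel domain of (p - q)^2 weighted by
d_p^a + d_q^a, where d_q is the Euclidean distance transform to the ground-
truth boundary, d_p the same for the prediction thresholded at 0.5, and
a = 2 (``HausdorffParams.dt_power``).  The adversarial terms are least-squares
(LSGAN): the generator drives D(G(x)) toward 1; the discriminator drives
D(y) toward 1 and D(G(x)) toward 0.

Every loss reduces by mean (or the normalised Dice sum) and also exposes the
gradient with respect to the prediction, so the hand-written training loop can
backpropagate; the distance transforms are treated as constants within a step
(no gradient flows through them).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

DICE_EPS = 1e-6
FOCAL_EPS = 1e-7


@dataclasses.dataclass
class LossWeights:
    """Weights of the integrated objective (printed defaults)."""

    dice: float = 10.0
    hausdorff: float = 0.0001
    focal: float = 10.0
    adversarial: float = 0.1

    def __post_init__(self):
        if min(self.dice, self.hausdorff, self.focal, self.adversarial) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclasses.dataclass
class FocalParams:
    alpha_t: float = 0.2
    gamma_f: float = 5.0

    def __post_init__(self):
        if not 0 < self.alpha_t < 1:
            raise ValueError("alpha_t must lie in (0, 1)")
        if self.gamma_f < 0:
            raise ValueError("gamma_f must be >= 0")


@dataclasses.dataclass
class HausdorffParams:
    #: exponent on the two distance transforms
    dt_power: float = 2.0

    def __post_init__(self):
        if self.dt_power <= 0:
            raise ValueError("dt_power must be > 0")


# ---------------------------------------------------------------------------


def dice_loss(pred: np.ndarray, mask: np.ndarray) -> float:
    """Soft Dice loss: 1 - 2 <p, q> / (sum p + sum q + eps)."""
    pred = np.asarray(pred, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    inter = float((pred * mask).sum())
    denom = float(pred.sum() + mask.sum()) + DICE_EPS
    return 1.0 - 2.0 * inter / denom


def dice_loss_grad(pred: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """d(dice_loss)/d(pred)."""
    pred = np.asarray(pred, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    inter = (pred * mask).sum()
    denom = pred.sum() + mask.sum() + DICE_EPS
    return (-2.0 * mask * denom + 2.0 * inter) / denom ** 2


def _boundary_distance(binary: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean distance to the mask boundary (0 on the boundary).

    The boundary is the set of foreground voxels with a background 6-neighbour
    (the volume border counting as background).  An empty mask has no
    boundary; its distance weight is defined as 0 everywhere so the term
    degrades gracefully to a plain squared error.
    """
    binary = binary.astype(bool)
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.float64)
    eroded = ndimage.binary_erosion(binary, structure=_STRUCT6(binary.ndim),
                                    border_value=0)
    boundary = binary & ~eroded
    return ndimage.distance_transform_edt(~boundary)


def _STRUCT6(ndim):
    return ndimage.generate_binary_structure(ndim, 1)


def hausdorff_dt_loss(pred: np.ndarray, mask: np.ndarray,
                      params: HausdorffParams = HausdorffParams()) -> float:
    """Distance-transform Hausdorff surrogate (mean over the voxel domain)."""
    val, _ = hausdorff_dt_loss_with_grad(pred, mask, params)
    return val


def hausdorff_dt_loss_with_grad(pred: np.ndarray, mask: np.ndarray,
                                params: HausdorffParams = HausdorffParams()):
    pred = np.asarray(pred, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    d_q = _boundary_distance(mask >= 0.5)
    d_p = _boundary_distance(pred >= 0.5)
    weight = d_p ** params.dt_power + d_q ** params.dt_power
    diff = pred - mask
    val = float((diff ** 2 * weight).mean())
    grad = 2.0 * diff * weight / diff.size
    return val, grad


def focal_loss(pred: np.ndarray, mask: np.ndarray,
               params: FocalParams = FocalParams()) -> float:
    """Mean focal loss; alpha_t weights foreground, 1 - alpha_t background."""
    val, _ = focal_loss_with_grad(pred, mask, params)
    return val


def focal_loss_with_grad(pred: np.ndarray, mask: np.ndarray,
                         params: FocalParams = FocalParams()):
    pred = np.clip(np.asarray(pred, dtype=np.float64), FOCAL_EPS, 1 - FOCAL_EPS)
    fg = np.asarray(mask, dtype=bool)
    p_t = np.where(fg, pred, 1.0 - pred)
    alpha = np.where(fg, params.alpha_t, 1.0 - params.alpha_t)
    g = params.gamma_f
    one_m = 1.0 - p_t
    loss = -alpha * one_m ** g * np.log(p_t)
    # d loss / d p_t, then chain through p_t = p or 1 - p
    dl_dpt = alpha * (g * one_m ** (g - 1) * np.log(p_t) - one_m ** g / p_t)
    dl_dp = np.where(fg, dl_dpt, -dl_dpt) / pred.size
    return float(loss.mean()), dl_dp


def lsgan_losses(d_on_fake: np.ndarray, d_on_real: np.ndarray
                 ) -> tuple[float, float]:
    """Least-squares adversarial objectives.

    Returns ``(g_loss, d_loss)`` where g_loss = mean (D(G(x)) - 1)^2 and
    d_loss = mean (D(y) - 1)^2 + mean D(G(x))^2.
    """
    fake = np.asarray(d_on_fake, dtype=np.float64)
    real = np.asarray(d_on_real, dtype=np.float64)
    if not (np.isfinite(fake).all() and np.isfinite(real).all()):
        raise ValueError("score maps must be finite")
    g_loss = float(((fake - 1.0) ** 2).mean())
    d_loss = float(((real - 1.0) ** 2).mean() + (fake ** 2).mean())
    return g_loss, d_loss


def integrated_loss(dice: float, hausdorff: float, focal: float, adv_g: float,
                    weights: LossWeights = LossWeights()) -> float:
    """Weighted sum of the four generator objectives."""
    parts = (dice, hausdorff, focal, adv_g)
    if not all(np.isfinite(parts)):
        raise ValueError("loss components must be finite")
    return (weights.dice * dice + weights.hausdorff * hausdorff
            + weights.focal * focal + weights.adversarial * adv_g)
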