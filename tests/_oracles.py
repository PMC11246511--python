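"""Independent brute-force oracles used by the test suite.

Everything here is written from the mathematical definitions alone (explicit
enumeration, all-pairs distances, dense attention matrices) and never calls
the implementation it checks.
"""

import numpy as np
from scipy.spatial.distance import cdist


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """[N, ndim] coordinates of foreground voxels with a background
    face-neighbour; the volume border counts as background."""
    mask = np.asarray(mask, dtype=bool)
    coords = []
    for idx in np.argwhere(mask):
        on_border = False
        for ax in range(mask.ndim):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if (nb[ax] < 0 or nb[ax] >= mask.shape[ax]
                        or not mask[tuple(nb)]):
                    on_border = True
        if on_border:
            coords.append(idx)
    return np.array(coords).reshape(-1, mask.ndim)


def distance_to_boundary(mask: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean distance to the mask boundary (all-pairs)."""
    bnd = boundary_voxels(mask)
    if len(bnd) == 0:
        return np.zeros(mask.shape)
    grid = np.indices(mask.shape).reshape(mask.ndim, -1).T
    d = cdist(grid, bnd).min(axis=1)
    return d.reshape(mask.shape)


def hausdorff_dt_loss(pred, mask, power=2.0):
    """Direct evaluation: mean of (p-q)^2 * (d_p^a + d_q^a)."""
    pred = np.asarray(pred, dtype=float)
    mask = np.asarray(mask, dtype=float)
    d_p = distance_to_boundary(pred >= 0.5)
    d_q = distance_to_boundary(mask >= 0.5)
    return float(((pred - mask) ** 2 * (d_p ** power + d_q ** power)).mean())


def focal_loss(pred, mask, alpha_t=0.2, gamma_f=5.0, eps=1e-7):
    pred = np.clip(np.asarray(pred, dtype=float), eps, 1 - eps)
    total = 0.0
    for p, m in zip(pred.ravel(), np.asarray(mask).ravel()):
        p_t = p if m else 1.0 - p
        a = alpha_t if m else 1.0 - alpha_t
        total += -a * (1.0 - p_t) ** gamma_f * np.log(p_t)
    return total / pred.size


def dice_loss(pred, mask, eps=1e-6):
    pred = np.asarray(pred, dtype=float)
    mask = np.asarray(mask, dtype=float)
    return 1.0 - 2.0 * (pred * mask).sum() / (pred.sum() + mask.sum() + eps)


def surface_distances_pooled(a, b, spacing):
    """All-pairs symmetric surface distances in mm, pooled both ways."""
    sa = boundary_voxels(a)
    sb = boundary_voxels(b)
    if len(sa) == 0 or len(sb) == 0:
        return None
    w = np.asarray(spacing, dtype=float)
    d_ab = cdist(sa * w, sb * w)
    return np.concatenate([d_ab.min(axis=1), d_ab.min(axis=0)])


def hd95(a, b, spacing=(1.0, 1.0, 1.0)):
    d = surface_distances_pooled(a, b, spacing)
    return None if d is None else float(np.percentile(d, 95))


def hausdorff_exact(a, b, spacing=(1.0, 1.0, 1.0)):
    d = surface_distances_pooled(a, b, spacing)
    return None if d is None else float(d.max())


def nsd(a, b, tol, spacing=(1.0, 1.0, 1.0)):
    d = surface_distances_pooled(a, b, spacing)
    return None if d is None else float((d <= tol).mean())


def dense_attention(x, theta_w, theta_b, phi_w, phi_b, sigma_w, sigma_b,
                    proj_w, proj_b):
    """Non-local block by materialising the full N x N attention matrix.

    ``x`` is [C, H, W]; the 1x1 convolution weights are [C_out, C_in] with
    bias [C_out].  Returns x + proj(softmax(theta^T phi) sigma^T).
    """
    c, h, w = x.shape
    n = h * w
    flat = x.reshape(c, n)
    q = theta_w @ flat + theta_b[:, None]    # [Ci, N]
    k = phi_w @ flat + phi_b[:, None]
    v = sigma_w @ flat + sigma_b[:, None]
    out = np.zeros_like(v)
    for i in range(n):                        # query position
        logits = np.array([q[:, i] @ k[:, j] for j in range(n)])
        weights = np.exp(logits)
        weights /= weights.sum()
        out[:, i] = sum(weights[j] * v[:, j] for j in range(n))
    y = proj_w @ out + proj_b[:, None]
    return x + y.reshape(c, h, w)
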