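"""Alternating adversarial training, per-vertebra inference, spine assembly.

Each optimisation step updates the discriminator once on (real target,
detached generator output) with the least-squares objective, then the
generator once on the integrated objective (Dice + Hausdorff-DT + Focal +
adversarial).  Losses are averaged per sample and over the batch; the
learning rate decays by a factor of 10 every 20 epochs.  Runs are
deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses as L
from . import metrics as M
from . import network
from .imaging import PatchPair
from .nn import Adam

DTYPE = np.float32


@dataclasses.dataclass
class TrainConfig:
    """Optimisation settings (defaults are the full-scale printed settings)."""

    epochs: int = 100
    batch_size: int = 8
    lr: float = 0.0001
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20
    adam_betas: tuple[float, float] = (0.5, 0.9)
    seed: int = 0
    patch_size: int = 120
    loss_weights: L.LossWeights = dataclasses.field(default_factory=L.LossWeights)
    focal: L.FocalParams = dataclasses.field(default_factory=L.FocalParams)
    hausdorff: L.HausdorffParams = dataclasses.field(default_factory=L.HausdorffParams)
    #: optional hard cap on total optimisation steps (None = epochs decide)
    max_steps: int | None = None
    # ablation axes
    use_dice: bool = True
    use_focal_hausdorff: bool = True
    use_adversarial: bool = True
    device: str = "cpu (single process)"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("epochs >= 1, batch_size >= 1, lr > 0 required")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in force during 0-indexed ``epoch``."""
        return self.lr * self.lr_decay_factor ** (epoch // self.lr_decay_every)


def desk_train_config(**overrides) -> TrainConfig:
    """CPU-scale preset matched to the desk generator (S = 32)."""
    kw = dict(patch_size=32, batch_size=2, lr=0.002, epochs=10, max_steps=200)
    kw.update(overrides)
    return TrainConfig(**kw)


def _stack(pairs: list[PatchPair]):
    pc = np.stack([p.coronal_patch for p in pairs]).astype(DTYPE)
    mc = np.stack([p.coronal_centroid_mask for p in pairs]).astype(DTYPE)
    ps = np.stack([p.sagittal_patch for p in pairs]).astype(DTYPE)
    ms = np.stack([p.sagittal_centroid_mask for p in pairs]).astype(DTYPE)
    tg = np.stack([p.target for p in pairs]).astype(DTYPE)
    return pc, mc, ps, ms, tg


def train(config: TrainConfig, pairs: list[PatchPair],
          gen_config: network.GeneratorConfig | None = None,
          disc_config: network.DiscriminatorConfig | None = None,
          checkpoint_dir=None):
    """Train generator and discriminator alternately on supervised pairs.

    Returns ``(generator, discriminator, log)`` where ``log`` is a DataFrame
    with one row per step (loss components, integrated g_loss, d_loss, lr).
    ``discriminator`` is None when adversarial training is ablated.
    """
    if not pairs:
        raise ValueError("training requires a nonempty list of pairs")
    if any(p.target is None for p in pairs):
        raise ValueError("all training pairs need targets")

    s = config.patch_size
    if pairs[0].size != s:
        raise ValueError(f"pairs have size {pairs[0].size}, config expects {s}")
    gen_config = gen_config or network.GeneratorConfig(patch_size=s)
    rng = np.random.default_rng(config.seed)
    gen = network.Generator(gen_config, rng)
    disc = None
    opt_d = None
    if config.use_adversarial:
        disc_config = disc_config or network.DiscriminatorConfig(patch_size=s)
        disc = network.Discriminator(disc_config, rng)
        opt_d = Adam(list(disc.parameters()), config.lr, config.adam_betas)
    opt_g = Adam(list(gen.parameters()), config.lr, config.adam_betas)

    w = config.loss_weights
    rows = []
    step = 0
    done = False
    for epoch in range(config.epochs):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), config.batch_size):
            batch = [pairs[i] for i in order[start:start + config.batch_size]]
            pc, mc, ps, ms, tg = _stack(batch)
            b = len(batch)

            gen.set_training(True)
            pred = gen.forward(pc, mc, ps, ms)

            # --- discriminator step (generator output detached) ------------
            d_loss = 0.0
            if disc is not None:
                disc.set_training(True)
                disc.zero_grad()
                s_real = disc.forward(tg)
                disc.backward(2.0 * (s_real - 1.0) / s_real.size)
                s_fake = disc.forward(pred)
                disc.backward(2.0 * s_fake / s_fake.size)
                _, d_loss = L.lsgan_losses(s_fake, s_real)
                opt_d.step(lr)

            # --- generator step --------------------------------------------
            gen.zero_grad()
            dpred = np.zeros_like(pred)
            dice_v = haus_v = focal_v = adv_v = 0.0
            for i in range(b):
                p_i, t_i = pred[i].astype(np.float64), tg[i].astype(np.float64)
                if config.use_dice:
                    dice_v += L.dice_loss(p_i, t_i) / b
                    dpred[i] += (w.dice / b) * L.dice_loss_grad(p_i, t_i)
                if config.use_focal_hausdorff:
                    hv, hg = L.hausdorff_dt_loss_with_grad(p_i, t_i, config.hausdorff)
                    fv, fg = L.focal_loss_with_grad(p_i, t_i, config.focal)
                    haus_v += hv / b
                    focal_v += fv / b
                    dpred[i] += (w.hausdorff / b) * hg + (w.focal / b) * fg
            if disc is not None:
                s_fake = disc.forward(pred)
                adv_v, _ = L.lsgan_losses(s_fake, np.ones(1))
                dvol = disc.backward(2.0 * (s_fake - 1.0) / s_fake.size)
                disc.zero_grad()  # discard D grads from the G pass
                dpred += w.adversarial * dvol
            g_loss = L.integrated_loss(dice_v, haus_v, focal_v, adv_v, w)
            gen.backward(dpred)
            opt_g.step(lr)

            if not np.isfinite(g_loss) or not np.isfinite(d_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"g_loss={g_loss}, d_loss={d_loss}")
            rows.append(dict(epoch=epoch, step=step, dice=dice_v,
                             hausdorff=haus_v, focal=focal_v, adv_g=adv_v,
                             g_loss=g_loss, d_loss=d_loss, lr=lr))
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        if checkpoint_dir is not None:
            ckdir = Path(checkpoint_dir)
            ckdir.mkdir(parents=True, exist_ok=True)
            network.save_checkpoint(ckdir / f"generator_ep{epoch:03d}.npz",
                                    gen, gen_config)
            if disc is not None:
                network.save_checkpoint(ckdir / f"discriminator_ep{epoch:03d}.npz",
                                        disc, disc_config)
        if done:
            break
    return gen, disc, pd.DataFrame(rows)


def reconstruct(gen: network.Generator, pair: PatchPair,
                threshold: float = 0.5) -> np.ndarray:
    """Binarised generator output for one pair (voxels with p >= threshold)."""
    prob = network.generator_forward(gen, pair)
    return prob >= threshold


def assemble_spine(recons: list[tuple[int, np.ndarray, tuple[int, int, int]]],
                   canvas_shape: tuple[int, int, int],
                   threshold: float = 0.5) -> np.ndarray:
    """Paste per-vertebra reconstructions into one labelled volume.

    ``recons`` holds ``(label_id, volume, offset)`` triples where ``volume``
    may be a probability or binary volume; voxels with probability >=
    ``threshold`` are pasted at ``offset``.  Overlaps go to the vertebra with
    the higher probability; exact ties to the later-indexed vertebra.
    """
    canvas = np.zeros(canvas_shape, dtype=np.int32)
    best = np.zeros(canvas_shape, dtype=np.float64)
    for label_id, vol, offset in recons:
        vol = np.asarray(vol, dtype=np.float64)
        src = tuple(slice(max(-o, 0), min(n - o, s))
                    for o, n, s in zip(offset, canvas_shape, vol.shape))
        dst = tuple(slice(s.start + o, s.stop + o)
                    for s, o in zip(src, offset))
        if any(s.start >= s.stop for s in dst):
            raise ValueError(f"offset {offset} places vertebra {label_id} "
                             f"entirely outside canvas {canvas_shape}")
        sub = vol[src]
        win = (sub >= threshold) & (sub >= best[dst])
        canvas_view = canvas[dst]
        best_view = best[dst]
        canvas_view[win] = label_id
        best_view[win] = sub[win]
    return canvas


def evaluate(gen: network.Generator, pairs: list[PatchPair],
             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
             threshold: float = 0.5, nsd_tol_mm: float = 1.0,
             reconstruct_fn=None) -> pd.DataFrame:
    """Per-vertebra Dice/HD95/NSD rows plus aggregates.

    ``reconstruct_fn(pair) -> binary volume`` may replace the generator (e.g.
    an oracle test double); empty predictions score Dice 0 with HD95/NSD
    flagged as NaN.
    """
    if any(p.target is None for p in pairs):
        raise ValueError("evaluation pairs need targets")
    fn = reconstruct_fn or (lambda pair: reconstruct(gen, pair, threshold))
    rows = []
    for pair in pairs:
        pred = fn(pair)
        tgt = pair.target.astype(bool)
        rows.append(dict(subject_id=pair.subject_id,
                         vertebra_label=pair.vertebra_label,
                         dice=M.dice_coeff(pred, tgt),
                         hd95=M.hd95(pred, tgt, spacing),
                         nsd=M.nsd(pred, tgt, nsd_tol_mm, spacing)))
    return M.metrics_table(rows)
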