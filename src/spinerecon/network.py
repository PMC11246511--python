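"""Bi-planar reconstruction networks.

The generator maps a (coronal, sagittal) pair of vertebra-centred radiograph
patches, each with a centroid-mask channel, to a soft 3D occupancy volume:

1. per-view *centroid fusion*: channel-concatenate patch and centroid mask,
   run a small convolutional stem, then a non-local self-attention block so
   the centroid annotation can modulate every pixel of the patch;
2. *2D-3D lifting*: duplicate the coronal feature along the anterior-posterior
   axis and the sagittal feature along the left-right axis (orthogonal
   parallel-beam views), then concatenate channels;
3. a 3D residual U-Net with batch normalisation and skip connections,
   finishing in a 1-channel sigmoid head.

The discriminator is a fully convolutional stack of stride-2 3D convolutions
that scores local patches of an occupancy volume as real or fake (no global
pooling), in the PatchGAN style.

Axis convention (package-wide): axis 0 = sagittal (left-right), axis 1 =
coronal (anterior-posterior), axis 2 = axial (inferior-superior).  The coronal
projection therefore lives on axes (0, 2) and the sagittal on axes (1, 2).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn


@dataclasses.dataclass
class GeneratorConfig:
    """Architecture of the generator.

    ``patch_size`` is the side S of the square input patches and of the cubic
    output volume (the full-scale setting is S = 120; the desk preset uses
    S = 32 so the whole pipeline runs on one CPU).  ``depth`` counts encoder
    levels of the 3D U-Net; S must be divisible by ``2 ** (depth - 1)``.
    The ablation flags disable the centroid-mask input channel and the
    non-local attention block while keeping every tensor shape unchanged.
    """

    patch_size: int = 120
    base_channels: int = 16
    depth: int = 4
    fusion_channels: int = 8
    use_centroid_mask: bool = True
    use_nonlocal: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.patch_size % (2 ** (self.depth - 1)):
            raise ValueError("patch_size must be divisible by 2**(depth-1)")


@dataclasses.dataclass
class DiscriminatorConfig:
    patch_size: int = 120
    base_channels: int = 8
    n_layers: int = 4          # stride-2 convolutions


def desk_generator_config(**overrides) -> GeneratorConfig:
    """Small preset that trains on one CPU in minutes."""
    kw = dict(patch_size=32, base_channels=8, depth=3, fusion_channels=4)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def desk_discriminator_config(**overrides) -> DiscriminatorConfig:
    kw = dict(patch_size=32, base_channels=4, n_layers=4)
    kw.update(overrides)
    return DiscriminatorConfig(**kw)


# ---------------------------------------------------------------------------
# lifting


def lift_to_3d(coronal_feat: np.ndarray, sagittal_feat: np.ndarray) -> np.ndarray:
    """Expand two orthogonal 2D feature maps into one 3D feature volume.

    ``coronal_feat``  [B, C1, S, S] over (sagittal, axial) axes is duplicated
    S times along the anterior-posterior axis; ``sagittal_feat`` [B, C2, S, S]
    over (coronal, axial) axes is duplicated along the left-right axis.  Both
    land in the shared (sagittal, coronal, axial) frame and are concatenated
    on the channel axis -> [B, C1+C2, S, S, S].
    """
    if coronal_feat.shape[2:] != sagittal_feat.shape[2:]:
        raise ValueError("views must share spatial size")
    s = coronal_feat.shape[2]
    cor = np.broadcast_to(coronal_feat[:, :, :, None, :],
                          coronal_feat.shape[:2] + (s, s, s))
    sag = np.broadcast_to(sagittal_feat[:, :, None, :, :],
                          sagittal_feat.shape[:2] + (s, s, s))
    return np.concatenate([cor, sag], axis=1)


def _lift_backward(dvol: np.ndarray, c1: int):
    """Adjoint of :func:`lift_to_3d`: sum over the duplicated axis."""
    return dvol[:, :c1].sum(axis=3), dvol[:, c1:].sum(axis=2)


# ---------------------------------------------------------------------------
# modules


class FusionStem(nn.Module):
    """Per-view centroid fusion: concat(patch, centroid mask) -> conv stem ->
    non-local attention.  Output keeps the S x S spatial size."""

    def __init__(self, config: GeneratorConfig, rng):
        f = config.fusion_channels
        self.config = config
        self.stem = nn.Sequential(nn.Conv2d(2, f, 3, rng=rng),
                                  nn.BatchNorm(f), nn.ReLU())
        self.attention = (nn.NonLocal2d(f, rng=rng)
                          if config.use_nonlocal else None)

    def forward(self, patch: np.ndarray, cmask: np.ndarray) -> np.ndarray:
        if patch.shape != cmask.shape:
            raise ValueError("patch and centroid mask shapes differ")
        if not self.config.use_centroid_mask:
            cmask = np.zeros_like(cmask)
        x = np.stack([patch, cmask], axis=1)
        y = self.stem.forward(x)
        if self.attention is not None:
            y = self.attention.forward(y)
        return y

    def backward(self, dy: np.ndarray) -> None:
        if self.attention is not None:
            dy = self.attention.backward(dy)
        self.stem.backward(dy)


class UNet3d(nn.Module):
    """Residual 3D U-Net: stride-2 conv downsampling, nearest-neighbour
    upsampling, channel-concatenated skip connections, sigmoid head."""

    def __init__(self, c_in: int, config: GeneratorConfig, rng):
        base, depth = config.base_channels, config.depth
        chs = [base * 2 ** i for i in range(depth)]
        self.enc = [nn.ResBlock3d(c_in if i == 0 else chs[i - 1], chs[i], rng)
                    for i in range(depth)]
        self.down = [nn.Conv3d(chs[i], chs[i], 3, stride=2, rng=rng)
                     for i in range(depth - 1)]
        self.up = [nn.Sequential(nn.Upsample3dNearest(),
                                 nn.Conv3d(chs[i + 1], chs[i], 3, rng=rng))
                   for i in range(depth - 1)]
        self.dec = [nn.ResBlock3d(2 * chs[i], chs[i], rng)
                    for i in range(depth - 1)]
        self.head = nn.Sequential(nn.Conv3d(chs[0], 1, 1, rng=rng), nn.Sigmoid())
        self.depth = depth

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for i in range(self.depth - 1):
            x = self.enc[i].forward(x)
            skips.append(x)
            x = self.down[i].forward(x)
        x = self.enc[-1].forward(x)
        for i in reversed(range(self.depth - 1)):
            x = self.up[i].forward(x)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i].forward(x)
        self._nskip = [s.shape[1] for s in skips]
        return self.head.forward(x)[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.head.backward(dy[:, None])
        dskips = [None] * (self.depth - 1)
        for i in range(self.depth - 1):
            dx = self.dec[i].backward(dx)
            c = self._nskip[i]
            dskips[i] = dx[:, :c]
            dx = self.up[i].backward(dx[:, c:])
        dx = self.enc[-1].backward(dx)
        for i in reversed(range(self.depth - 1)):
            dx = self.down[i].backward(dx)
            dx = self.enc[i].backward(dx + dskips[i])
        return dx


class Generator(nn.Module):
    """Full generator; forward returns a [B, S, S, S] soft occupancy volume."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        self.stem_coronal = FusionStem(config, rng)
        self.stem_sagittal = FusionStem(config, rng)
        self.unet = UNet3d(2 * config.fusion_channels, config, rng)

    def forward(self, coronal_patch, coronal_mask, sagittal_patch, sagittal_mask):
        cor = self.stem_coronal.forward(coronal_patch, coronal_mask)
        sag = self.stem_sagittal.forward(sagittal_patch, sagittal_mask)
        return self.unet.forward(lift_to_3d(cor, sag))

    def backward(self, dpred: np.ndarray) -> None:
        dvol = self.unet.backward(dpred)
        dcor, dsag = _lift_backward(dvol, self.config.fusion_channels)
        self.stem_coronal.backward(dcor)
        self.stem_sagittal.backward(dsag)


class Discriminator(nn.Module):
    """Stride-2 3D conv stack emitting a spatial real/fake score map."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        self.config = config
        layers: list[nn.Module] = [
            nn.Conv3d(1, config.base_channels, 3, stride=2, rng=rng),
            nn.LeakyReLU(0.2)]
        c = config.base_channels
        for _ in range(config.n_layers - 1):
            layers += [nn.Conv3d(c, 2 * c, 3, stride=2, rng=rng),
                       nn.BatchNorm(2 * c), nn.LeakyReLU(0.2)]
            c *= 2
        layers.append(nn.Conv3d(c, 1, 3, rng=rng))
        self.net = nn.Sequential(*layers)

    def forward(self, volume: np.ndarray) -> np.ndarray:
        return self.net.forward(volume[:, None])[:, 0]

    def backward(self, dscore: np.ndarray) -> np.ndarray:
        return self.net.backward(dscore[:, None])[:, 0]


# ---------------------------------------------------------------------------
# functional surface


def nonlocal_block(x: np.ndarray, block: nn.NonLocal2d) -> np.ndarray:
    """Apply a non-local attention block to a single [C, H, W] feature map."""
    return block.forward(x[None])[0]


def centroid_fusion(patch: np.ndarray, cmask: np.ndarray,
                    stem: FusionStem) -> np.ndarray:
    """Fuse one [S, S] patch with its centroid mask through a view stem."""
    stem.set_training(False)
    return stem.forward(patch[None], cmask[None])[0]


def generator_forward(gen: Generator, pair) -> np.ndarray:
    """Evaluate the generator on one PatchPair (evaluation mode)."""
    gen.set_training(False)
    out = gen.forward(pair.coronal_patch[None].astype(np.float32),
                      pair.coronal_centroid_mask[None].astype(np.float32),
                      pair.sagittal_patch[None].astype(np.float32),
                      pair.sagittal_centroid_mask[None].astype(np.float32))[0]
    return out


def discriminator_forward(disc: Discriminator, volume: np.ndarray) -> np.ndarray:
    disc.set_training(False)
    return disc.forward(volume[None].astype(np.float32))[0]


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, module: nn.Module, config) -> None:
    """Write named parameter arrays plus the architecture config to ``path``
    (NumPy .npz; the config is embedded as a JSON string)."""
    state = module.state_dict()
    state["__config__"] = np.array(json.dumps(dataclasses.asdict(config)))
    np.savez(path, **state)


def load_checkpoint(path, factory, config_cls, seed: int = 0):
    """Rebuild ``factory(config, rng)`` from a checkpoint and load weights."""
    with np.load(path, allow_pickle=False) as data:
        state = {k: data[k] for k in data.files}
    config = config_cls(**json.loads(str(state.pop("__config__"))))
    module = factory(config, np.random.default_rng(seed))
    module.load_state_dict(state)
    return module, config
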