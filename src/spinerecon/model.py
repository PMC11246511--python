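"""Model/Results interface over the training pipeline.

``ReconstructionModel`` holds the supervised patch pairs and every
configuration choice; ``fit()`` runs the alternating adversarial optimisation
and returns a ``ReconstructionResults`` carrying the fitted networks, the
per-step training log, and evaluation / reconstruction / assembly methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import importlib

from . import network
from .imaging import PatchPair, build_pairs
from .phantom import SpineRecord

# the package re-exports the train() function under the module's name, so
# resolve the module object explicitly
_train = importlib.import_module(__name__.rsplit(".", 1)[0] + ".train")


class ReconstructionModel:
    """Bi-planar vertebra reconstruction model bound to training data."""

    def __init__(self, pairs: list[PatchPair],
                 config: _train.TrainConfig | None = None,
                 gen_config: network.GeneratorConfig | None = None,
                 disc_config: network.DiscriminatorConfig | None = None):
        if not pairs:
            raise ValueError("no training pairs")
        size = pairs[0].size
        self.pairs = pairs
        self.config = config or _train.TrainConfig(patch_size=size)
        self.gen_config = gen_config or network.GeneratorConfig(patch_size=size)
        self.disc_config = disc_config or network.DiscriminatorConfig(patch_size=size)

    @classmethod
    def from_records(cls, records: list[SpineRecord], size: int,
                     radius: int = 4, **kwargs) -> "ReconstructionModel":
        pairs = [p for r in records for p in build_pairs(r, size=size, radius=radius)]
        return cls(pairs, **kwargs)

    def fit(self, seed: int | None = None, checkpoint_dir=None
            ) -> "ReconstructionResults":
        config = self.config
        if seed is not None:
            config = dataclasses_replace(config, seed=seed)
        gen, disc, log = _train.train(config, self.pairs, self.gen_config,
                                      self.disc_config, checkpoint_dir)
        return ReconstructionResults(self, config, gen, disc, log)


def dataclasses_replace(config, **kw):
    import dataclasses
    return dataclasses.replace(config, **kw)


class ReconstructionResults:
    """Fitted networks plus the training log and evaluation helpers."""

    def __init__(self, model, config, generator, discriminator, log: pd.DataFrame):
        self.model = model
        self.config = config
        self.generator = generator
        self.discriminator = discriminator
        self.log = log

    # -- inference ----------------------------------------------------------
    def predict(self, pair: PatchPair) -> np.ndarray:
        """Soft occupancy volume in [0, 1] for one pair."""
        return network.generator_forward(self.generator, pair)

    def reconstruct(self, pair: PatchPair, threshold: float = 0.5) -> np.ndarray:
        return _train.reconstruct(self.generator, pair, threshold)

    def assemble(self, pairs: list[PatchPair], canvas_shape,
                 labels: list[int] | None = None,
                 threshold: float = 0.5) -> np.ndarray:
        labels = labels or list(range(1, len(pairs) + 1))
        recons = [(lab, self.predict(p), p.crop_offset)
                  for lab, p in zip(labels, pairs)]
        return _train.assemble_spine(recons, canvas_shape, threshold)

    def evaluate(self, pairs: list[PatchPair], **kwargs) -> pd.DataFrame:
        return _train.evaluate(self.generator, pairs, **kwargs)

    # -- reporting ------------------------------------------------------------
    def summary(self, eval_pairs: list[PatchPair] | None = None) -> str:
        n_params = sum(p.value.size for _, p in self.generator.parameters())
        last = self.log.iloc[-1]
        lines = [
            "Bi-planar vertebra reconstruction — fit summary",
            "=" * 48,
            f"training pairs:        {len(self.model.pairs)}",
            f"patch size S:          {self.config.patch_size}",
            f"generator parameters:  {n_params}",
            f"steps run:             {len(self.log)} "
            f"(epochs {self.log.epoch.nunique()}, batch {self.config.batch_size})",
            f"final losses:          dice={last.dice:.4f} "
            f"hausdorff={last.hausdorff:.4f} focal={last.focal:.4f} "
            f"adv={last.adv_g:.4f} (integrated {last.g_loss:.4f})",
            f"final learning rate:   {last.lr:g}",
        ]
        if eval_pairs:
            table = self.evaluate(eval_pairs)
            overall = table[table.vertebra_label == "overall"].iloc[0]
            lines.append(
                f"held-out (n={int(overall['n'])}):   dice={overall.dice:.4f} "
                f"hd95={overall.hd95:.4f} mm nsd={overall.nsd:.4f}")
        return "\n".join(lines)

    def save(self, gen_path, disc_path=None) -> None:
        network.save_checkpoint(gen_path, self.generator, self.model.gen_config)
        if disc_path is not None and self.discriminator is not None:
            network.save_checkpoint(disc_path, self.discriminator,
                                    self.model.disc_config)
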