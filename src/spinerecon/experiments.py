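"""Reference desk-scale experiment: phantom recovery on one CPU.

The study conditions are fixed: 13 phantom spines of 4 vertebrae each
(10 subjects -> 40 training pairs, 3 held-out subjects -> 12 evaluation
pairs) at patch size S = 32, trained for 200 alternating adversarial steps
with the desk presets.  The random-init baseline evaluates an untrained
generator on the same held-out pairs.
"""

from __future__ import annotations

import numpy as np

from . import network
from .imaging import build_pairs
from .phantom import PhantomSpec, make_spine_phantom
from .train import desk_train_config, evaluate, train

N_TRAIN_RECORDS = 10
N_TEST_RECORDS = 3
PATCH_SIZE = 32
MASK_RADIUS = 2
STEPS = 200


def desk_dataset(seed: int):
    """Phantom train/held-out patch pairs under the fixed study conditions."""
    records = [make_spine_phantom(PhantomSpec(seed=seed * 1000 + i))
               for i in range(N_TRAIN_RECORDS + N_TEST_RECORDS)]
    train_pairs = [p for r in records[:N_TRAIN_RECORDS]
                   for p in build_pairs(r, size=PATCH_SIZE, radius=MASK_RADIUS)]
    held_pairs = [p for r in records[N_TRAIN_RECORDS:]
                  for p in build_pairs(r, size=PATCH_SIZE, radius=MASK_RADIUS)]
    return train_pairs, held_pairs


def _overall(table):
    return table[table.vertebra_label == "overall"].iloc[0]


def desk_recovery_experiment(seed: int) -> dict:
    """Train at desk scale and score held-out reconstruction quality.

    Returns held-out Dice/HD95/NSD for the trained generator and the Dice of
    an untrained (random-init) generator, plus sizes.
    """
    train_pairs, held_pairs = desk_dataset(seed)
    gcfg = network.desk_generator_config()
    dcfg = network.desk_discriminator_config()

    baseline = network.Generator(gcfg, np.random.default_rng(seed))
    base = _overall(evaluate(baseline, held_pairs))

    config = desk_train_config(seed=seed, max_steps=STEPS)
    gen, _, log = train(config, train_pairs, gcfg, dcfg)
    overall = _overall(evaluate(gen, held_pairs))
    return dict(seed=seed,
                n_train_pairs=len(train_pairs),
                n_held_pairs=len(held_pairs),
                steps=len(log),
                dice=float(overall.dice),
                hd95_mm=float(overall.hd95),
                nsd=float(overall.nsd),
                dice_random_init=float(base.dice))
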