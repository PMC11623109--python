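"""Desk-scale learning surrogate.

A reduced network (filter schedule 8-128) trained for at most 30 epochs on
64x64 high-contrast phantoms stands in for full-scale clinical training: it
exercises the entire pipeline (phantom generation, BCE/Adam optimisation,
plateau scheduling, held-out evaluation) at a size a single CPU handles in
minutes.  The conditions — contrast 0.7, 64 training / 4 validation / 8
held-out phantoms, reduced filters, <= 30 epochs — are fixed so results are
comparable across seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .graph import ModelConfig
from .metrics import MetricReport
from .phantom import PhantomParams, Sample, make_sample
from .train import Hyperparams, TrainHistory, evaluate, fit
from .network import build_network

__all__ = ["surrogate_phantoms", "run_learning_surrogate",
           "SURROGATE_CONFIG"]

SURROGATE_CONFIG = ModelConfig(input_height=64, input_width=64,
                               filter_schedule=(8, 16, 32, 64, 128))

SURROGATE_CONTRAST = 0.7
N_TRAIN, N_VAL, N_TEST = 64, 4, 8


def surrogate_phantoms(n: int, seed: int, *, size: int = 64,
                       contrast: float = SURROGATE_CONTRAST) -> list[Sample]:
    """n high-contrast lesion phantoms, alternating benign/malignant."""
    seeds = np.random.SeedSequence(seed).generate_state(max(n, 1)) % (2 ** 31)
    return [make_sample(PhantomParams.for_class(
        "benign" if i % 2 == 0 else "malignant", height=size, width=size,
        seed=int(seeds[i]), lesion_contrast=contrast))
        for i in range(n)]


def run_learning_surrogate(seed: int, epochs: int = 30
                           ) -> tuple[MetricReport, TrainHistory]:
    """Train the reduced model on the fixed surrogate task and return the
    held-out metric report plus the training history."""
    if epochs > 30:
        raise ValueError("the surrogate budget is at most 30 epochs")
    cfg = replace(SURROGATE_CONFIG, seed=seed)
    train_set = surrogate_phantoms(N_TRAIN, 100 + seed)
    val_set = surrogate_phantoms(N_VAL, 200 + seed)
    test_set = surrogate_phantoms(N_TEST, 300 + seed)
    hp = Hyperparams(epochs=epochs, batch_size=8, seed=seed)
    net, history = fit(build_network(cfg), train_set, val_set, hp)
    report = evaluate(net, test_set)
    return report, history
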