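"""Parameter and FLOP accounting.

``count_parameters`` enumerates every trainable weight.  ``count_flops``
traces one forward pass and accumulates multiply-accumulate counts with the
conventions common to FLOP profilers for segmentation networks (thop-style):
convolutions, linear projections and the selective scan are counted (one MAC
reported as one FLOP); normalisation layers, activations, elementwise sums
and FFTs are not.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import EncoderConfig
from .model import AblationFlags, SGNet
from .nn.functional import count_macs


def count_parameters(module: nn.Module) -> int:
    """Total number of trainable scalar parameters."""
    return module.num_parameters()


def count_flops(model: SGNet, batch: int = 1) -> int:
    """MACs of one forward pass at the model's configured input size."""
    size = model.input_size
    x = nn.Tensor(np.zeros((batch, 3, size, size), dtype=np.float32))
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad(), count_macs() as counter:
            model(x)
    finally:
        model.train(was_training)
    return counter.macs


def profile(encoder_config: EncoderConfig | None = None,
            input_size: int = 256, flags: AblationFlags | None = None,
            seed: int = 0) -> tuple[int, int]:
    """Build the full model and return (parameter count, forward MACs)."""
    nn.init.seed_all(seed)
    model = SGNet(input_size=input_size,
                  encoder_config=encoder_config or EncoderConfig(),
                  flags=flags)
    return count_parameters(model), count_flops(model)
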