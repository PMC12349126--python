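"""Parameter and FLOP budget of the full state-space model.

Builds the complete network (VMamba-style encoder, depths [2,2,9,2], plus
all four decoder-side modules) for 256x256 input and traces one forward
pass.  Takes ~30 s on one CPU; the cheap conv backbone profiles in a
second.
"""

from sgnet import nn
from sgnet.backbone import EncoderConfig
from sgnet.model import SGNet
from sgnet.profiling import count_flops, count_parameters

for variant in ("test_conv", "vmamba_tiny"):
    nn.init.seed_all(0)
    model = SGNet(input_size=256,
                  encoder_config=EncoderConfig(variant=variant))
    params = count_parameters(model)
    macs = count_flops(model)
    print(f"{variant:12s}  {params / 1e6:6.2f} M params   "
          f"{macs / 1e9:5.2f} GFLOPs @ 256x256")
# FLOPs follow the usual profiler convention (one multiply-accumulate = one
# FLOP; convolutions, projections and the selective scan are counted).
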