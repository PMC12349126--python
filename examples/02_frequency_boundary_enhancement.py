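"""The learnable Fourier filter at the heart of boundary enhancement.

The frequency branch computes IRFFT(RFFT(x) * W) with a learnable complex
weight map W.  Two limiting cases make its behaviour concrete: a unit
filter is an exact identity, and zeroing only the DC bin subtracts the
spatial mean (a crude high-pass that removes illumination offset).
"""

import numpy as np

from sgnet.nn import Tensor, frequency_filter

x = np.arange(16, dtype=float).reshape(1, 1, 4, 4)

unit_r = Tensor(np.ones((1, 4, 3)))
unit_i = Tensor(np.zeros((1, 4, 3)))
y = frequency_filter(Tensor(x), unit_r, unit_i)
print("unit filter max |y - x|:", float(np.abs(y.data - x).max()))

no_dc_r = Tensor(np.ones((1, 4, 3)))
no_dc_r.data[0, 0, 0] = 0.0          # zero the (u=0, v=0) bin
y = frequency_filter(Tensor(x), no_dc_r, unit_i)
print("DC-suppressed output mean:", float(y.data.mean()))
print("matches x - mean(x):",
      bool(np.allclose(y.data, x - x.mean(), atol=1e-10)))

# In the network one such filter per channel and pyramid level is learned
# end-to-end (initialised at 1+0i, i.e. as an identity), letting the model
# attenuate hair-like high-frequency noise while keeping lesion structure.
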