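"""Gaussian delay kernels: how a synaptic delay becomes a temporal kernel.

Builds one synapse with weight w = 1.5 and delay d = 5, prints its kernel
at a broad and a narrow kernel width, and pushes a single spike through it.
"""

import numpy as np

from snndelays import DelayedSynapseLayer, build_delay_kernels, delayed_current

for sigma in (6.0, 0.3):
    layer = DelayedSynapseLayer(
        weights=np.array([[1.5]]), delays=np.array([[5.0]]), T_d=25, sigma=sigma
    )
    k = build_delay_kernels(layer)[0, 0]
    print(f"sigma = {sigma:4.1f}: kernel sum = {k.sum():.6f} (equals the weight), "
          f"peak at tap {k.argmax()} (= T_d - d - 1 = 19)")

# a spike at t = 10 arrives d + 1 = 6 steps later
spikes = np.zeros((40, 1))
spikes[10, 0] = 1.0
current = delayed_current(spikes, layer)
print(f"single spike at t=10 -> postsynaptic current peaks at t={current[:, 0].argmax()}"
      " (delay 5 plus one conduction step)")
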