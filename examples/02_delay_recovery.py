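"""Recovering planted synaptic delays by gradient descent.

Generates spike rasters whose target currents were produced by a known
(weight, delay) matrix, then fits a delayed layer by mean-squared error
with the kernel width annealed from broad to narrow.  Prints the fraction
of delays recovered to within one timestep — the headline delay-learning
property.  Runs in about half a minute.
"""

import numpy as np

from snndelays import make_planted_delay_task
from snndelays.training import delay_recovery_fraction, fit_delay_layer

task = make_planted_delay_task(
    n_pre=12, n_post=4, T=80, n_samples=800, rate=0.1,
    rng=np.random.default_rng(0),
)
layer, history = fit_delay_layer(task, epochs=40, batch_size=200, seed=0)

frac = delay_recovery_fraction(layer, task)
print(f"training loss: {history['loss'].iloc[0]:.4f} -> {history['loss'].iloc[-1]:.4f}")
print(f"delays recovered within +-1 step: {frac:.1%} of {task.true_delays.size}")
print("a high fraction means the Gaussian-kernel parameterisation lets plain "
      "gradient descent find the true conduction delays")
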