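"""Structural spatio-temporal receptive fields of a trained (or untrained) network.

A *structural* receptive field summarizes, for one output class, where
excitation and inhibition arrive in input space and time — built from the
learned weights and delays themselves rather than from stimulus responses.

For each hidden neuron a panel is drawn with input neurons on the rows and
delay bins on the columns: each active input->hidden synapse places one
point at the column given by its (rounded) delay, signed by its weight
(+1 excitatory, -1 inhibitory; optionally carrying the weight magnitude).
The class receptive field is the sum of these panels over hidden neurons,
each scaled by the hidden->output weight and shifted right by the rounded
hidden->output delay, on a canvas wide enough that no shift truncates mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SpikingDelayNet

__all__ = [
    "ReceptiveField",
    "hidden_panel",
    "output_receptive_field",
    "all_receptive_fields",
    "plot_receptive_field",
]


@dataclass
class ReceptiveField:
    """Signed input-neuron x delay-bin matrix for one output class."""

    matrix: np.ndarray
    class_id: int
    bin_width: int = 1


def hidden_panel(
    model: SpikingDelayNet, hidden_idx: int, magnitude: bool = False
) -> np.ndarray:
    """Panel ``(n_inputs, T_d + 1)`` for one hidden neuron.

    Each active input synapse contributes its weight's sign (or, with
    ``magnitude=True``, the signed weight itself) at the column given by
    its rounded delay.  Dormant synapses contribute nothing.
    """
    cfg = model.cfg
    if not (0 <= hidden_idx < cfg.n_hidden):
        raise IndexError(f"hidden index {hidden_idx} out of range [0, {cfg.n_hidden})")
    w = model.layer1.weights()[hidden_idx]  # (n_inputs,)
    d = model.layer1.delays[hidden_idx]
    panel = np.zeros((cfg.n_inputs, cfg.T_d + 1))
    active = np.flatnonzero(w != 0.0)
    cols = np.rint(d[active]).astype(int)
    vals = w[active] if magnitude else np.sign(w[active])
    np.add.at(panel, (active, cols), vals)
    return panel


def output_receptive_field(
    model: SpikingDelayNet, output_idx: int, magnitude: bool = False
) -> ReceptiveField:
    """Receptive field of one output class.

    Canvas width is ``(T_d + 1) + T_d``: unshifted panels occupy columns
    ``0..T_d`` and a hidden->output delay of ``D`` shifts a panel ``D``
    columns toward larger total delay.
    """
    cfg = model.cfg
    if not (0 <= output_idx < cfg.n_outputs):
        raise IndexError(f"output index {output_idx} out of range [0, {cfg.n_outputs})")
    width = (cfg.T_d + 1) + cfg.T_d
    rf = np.zeros((cfg.n_inputs, width))
    w_out = model.layer2.weights()[output_idx]  # (n_hidden,)
    d_out = model.layer2.delays[output_idx]
    for h in np.flatnonzero(w_out != 0.0):
        shift = int(np.rint(d_out[h]))
        rf[:, shift : shift + cfg.T_d + 1] += w_out[h] * hidden_panel(model, h, magnitude)
    return ReceptiveField(matrix=rf, class_id=output_idx)


def all_receptive_fields(model: SpikingDelayNet, magnitude: bool = False) -> list[ReceptiveField]:
    """Receptive fields for every output class."""
    return [
        output_receptive_field(model, c, magnitude) for c in range(model.cfg.n_outputs)
    ]


def plot_receptive_field(rf: ReceptiveField, path=None, ax=None):
    """Render a receptive field as a blue/red diverging heatmap.

    Red marks net excitation, blue net inhibition; rows are input neurons,
    columns total delay (input delay plus hidden->output shift).  Saves to
    ``path`` if given, else returns the axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    vmax = np.abs(rf.matrix).max() or 1.0
    im = ax.imshow(
        rf.matrix, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
        aspect="auto", interpolation="nearest",
    )
    ax.set_xlabel("total delay (timesteps)")
    ax.set_ylabel("input neuron")
    ax.set_title(f"class {rf.class_id}")
    ax.figure.colorbar(im, ax=ax, label="excitation (+) / inhibition (-)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        return None
    return ax
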