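"""Diagnostic plots: atom montages, DX accuracy curves, ROC-style summaries."""

from __future__ import annotations

import numpy as np

from .dictlearn import StructuredDictionary
from .features import DXRanking


def plot_atoms(dictionary: StructuredDictionary, s: int, t: int, block: str = "p",
               n_atoms: int = 25, ax=None):
    """Render the first atoms of a block as an s x (s*t) montage grid: each
    atom's t timepoint slices are laid side by side."""
    import matplotlib.pyplot as plt

    D = {"p": dictionary.D_p, "t": dictionary.D_t, "s": dictionary.D_s}[block]
    n_atoms = min(n_atoms, D.shape[1])
    ncols = int(np.ceil(np.sqrt(n_atoms)))
    nrows = int(np.ceil(n_atoms / ncols))
    if ax is None:
        _, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 2 * nrows / t))
    else:
        axes = np.asarray(ax)
    axes = np.atleast_1d(axes).ravel()
    for i in range(n_atoms):
        atom = D[:, i].reshape(t, s, s)
        montage = np.hstack([atom[j] for j in range(t)])
        axes[i].imshow(montage, cmap="gray")
        axes[i].set_axis_off()
    for j in range(n_atoms, len(axes)):
        axes[j].set_axis_off()
    return axes[0].figure


def plot_accuracy_curve(ranking: DXRanking, ax=None):
    """CV accuracy versus number of top-DX-ranked features."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    k = np.arange(1, len(ranking.accuracy_curve) + 1)
    ax.plot(k, ranking.accuracy_curve, lw=1)
    ax.axvline(len(ranking.selected), color="r", ls="--", lw=1,
               label=f"selected = {len(ranking.selected)}")
    ax.set_xlabel("top-ranked features")
    ax.set_ylabel("CV accuracy")
    ax.legend()
    return ax.figure
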