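"""Small matplotlib renderings of the standard result displays."""

from __future__ import annotations

import numpy as np

from .decoding import ClassifierReport
from .geometry import DistanceMatrix
from .surrogates import SignificanceResult

__all__ = ["plot_confusion", "plot_distance_matrix", "plot_null_histogram"]


def plot_confusion(report: ClassifierReport, ax=None):
    """Row-normalized confusion matrix (% of each true class)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    im = ax.imshow(report.confusion, vmin=0, vmax=100, cmap="Blues")
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=90)
    ax.set_yticks(range(len(report.classes)), report.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("spoken")
    ax.figure.colorbar(im, ax=ax, label="% of trials")
    return ax


def plot_distance_matrix(dm: DistanceMatrix, ax=None):
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    v = float(np.abs(dm.M).max())
    im = ax.imshow(dm.M, cmap="RdBu_r", vmin=-v, vmax=v)
    ax.set_xticks(range(len(dm.labels)), dm.labels, rotation=90)
    ax.set_yticks(range(len(dm.labels)), dm.labels)
    ax.figure.colorbar(im, ax=ax, label="neural distance (Hz)")
    return ax


def plot_null_histogram(result: SignificanceResult, ax=None):
    """Surrogate R^2 null distribution with the observed value marked."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    ax.hist(result.null_R2, bins=30, color="tab:brown", alpha=0.8,
            label="surrogates")
    ax.axvline(result.observed_R2, color="tab:blue", lw=2,
               label=f"observed (p={result.p:.3g})")
    ax.set_xlabel(r"rotatory fit $R^2$")
    ax.set_ylabel("surrogate count")
    ax.legend()
    return ax
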