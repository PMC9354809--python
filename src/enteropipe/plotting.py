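"""Minimal ordination plot for smoke-testing; not figure-quality output."""

from __future__ import annotations

import numpy as np


def plot_biplot(ordination, labels=None, envfit_results=None, path=None):
    """Scatter the first two PCoA axes, colored by cluster label, with
    optional envfit arrows.  Returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = ordination.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(x[:, 0], x[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(x[m, 0], x[m, 1], s=12, label=str(lab))
        ax.legend(fontsize=7)
    if envfit_results:
        scale = 0.8 * np.abs(x[:, :2]).max()
        for e in envfit_results:
            if np.any(np.isnan(e.direction)):
                continue
            dx, dy = e.direction[0] * scale * e.r_squared, e.direction[1] * scale * e.r_squared
            ax.annotate(
                e.variable, (dx, dy),
                arrowprops=dict(arrowstyle="<-", color="gray"), xytext=(0, 0),
                textcoords="data", fontsize=7,
            )
    prop = ordination.proportion_explained
    ax.set_xlabel(f"PCo1 ({prop[0]:.1%})")
    if len(prop) > 1:
        ax.set_ylabel(f"PCo2 ({prop[1]:.1%})")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
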