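"""Display-only plots. Smoothing here never feeds any statistic."""

from __future__ import annotations

import numpy as np


def _rolling_mean(y: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or len(y) < k:
        return y
    kernel = np.ones(k) / k
    return np.convolve(y, kernel, mode="same")


def plot_fdm_scaffolds(fdm_table, path=None, smooth: int = 21, ax=None):
    """f_dM along each scaffold with a rolling-mean overlay."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    scaffolds = list(dict.fromkeys(fdm_table["scaffold"]))
    fig, axes = plt.subplots(
        len(scaffolds), 1, figsize=(9, 2.2 * len(scaffolds)), squeeze=False
    )
    for ax_i, scaffold in zip(axes[:, 0], scaffolds):
        sub = fdm_table[fdm_table["scaffold"] == scaffold]
        mid = (sub["start"] + sub["end"]) / 2
        ax_i.axhline(0, color="grey", lw=0.5)
        ax_i.plot(mid, sub["fdm"], ".", ms=2, alpha=0.4)
        y = sub["fdm"].to_numpy(dtype=float)
        if np.isfinite(y).all() and len(y) > smooth:
            ax_i.plot(mid, _rolling_mean(y, smooth), "-", lw=1.2)
        ax_i.set_ylabel("f_dM")
        ax_i.set_title(scaffold, fontsize=8)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_fbranch(fb, path=None):
    """Heatmap of the f-branch matrix; NaN cells (invalid tests) greyed."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(fb.tips), 1 + 0.5 * len(fb.branches)))
    masked = np.ma.masked_invalid(fb.values)
    cmap = plt.cm.viridis.copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, cmap=cmap, aspect="auto")
    ax.set_xticks(range(len(fb.tips)), fb.tips, rotation=45, ha="right")
    ax.set_yticks(
        range(len(fb.branches)), [",".join(sorted(b)) for b in fb.branches]
    )
    for i in range(fb.values.shape[0]):
        for j in range(fb.values.shape[1]):
            if fb.significant[i, j]:
                ax.text(j, i, "*", ha="center", va="center", color="white")
    fig.colorbar(im, ax=ax, label="f_b")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
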