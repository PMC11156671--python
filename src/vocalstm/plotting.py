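"""Basic map and ROC figures (temporal Hz on x, spectral cyc/kHz on y)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_map", "plot_roc"]


def plot_map(values, spectral_axis, temporal_axis, ax=None, smooth_sd: float = 0.0, **imshow_kw):
    """Render a modulation-plane map. ``smooth_sd`` (grid steps) applies a
    Gaussian blur for presentation only; stored maps stay raw."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = np.asarray(values, dtype=float)
    if smooth_sd > 0:
        from scipy.ndimage import gaussian_filter

        v = gaussian_filter(np.nan_to_num(v), sigma=smooth_sd)
    extent = (temporal_axis[0], temporal_axis[-1], spectral_axis[0], spectral_axis[-1])
    im = ax.imshow(v, origin="lower", aspect="auto", extent=extent, **imshow_kw)
    ax.set_xlabel("temporal modulation (Hz)")
    ax.set_ylabel("spectral modulation (cyc/kHz)")
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_roc(rocs: dict, ax=None):
    """Overlay per-group ROC curves with the chance diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, roc in rocs.items():
        ax.plot(roc["fpr"], roc["tpr"], lw=1, label=f"{g} (AUC={roc['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if len(rocs) <= 8:
        ax.legend(fontsize="small")
    return ax
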