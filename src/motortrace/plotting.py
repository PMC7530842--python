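"""Optional plotting helpers (visualization only, never analysis)."""

from __future__ import annotations

import numpy as np


def plot_mes_timeline(t, mes, smooth_s: float = 2.0, sampling_rate: float = 1.0, ax=None):
    """MES over time with a Gaussian smoothing overlay.

    Smoothing (sigma ``smooth_s`` seconds at ``sampling_rate`` points/s) is
    applied for display only; analyses always use the raw per-epoch scores.
    """
    import matplotlib.pyplot as plt
    from scipy.ndimage import gaussian_filter1d

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = np.asarray(t, dtype=float)
    mes = np.asarray(mes, dtype=float)
    ax.plot(t, mes, lw=0.6, alpha=0.5, color="gray", label="MES per epoch")
    ax.plot(
        t,
        gaussian_filter1d(mes, sigma=max(smooth_s * sampling_rate, 1e-9)),
        lw=1.8,
        color="C3",
        label=f"Gaussian-smoothed ({smooth_s:g} s)",
    )
    ax.axhline(0.0, color="k", lw=0.6, ls=":")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("MES")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_weight_profile(weights, ax=None, **kwargs):
    """Polar plot of one subject's (or group-mean) metric weights."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    names = list(weights.index)
    vals = np.asarray(weights, dtype=float)
    ang = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    ax.plot(np.r_[ang, ang[:1]], np.r_[vals, vals[:1]], **kwargs)
    ax.set_xticks(ang)
    ax.set_xticklabels(names, fontsize=7)
    return ax
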