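"""Optional plotting helpers for transforms and benchmark tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_spectrogram(power, frequencies, fs, ax=None, **imshow_kw):
    """Log-frequency spectrogram of a (n_freq, n_times) power matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n_times = power.shape[1]
    ax.imshow(
        power,
        origin="lower",
        aspect="auto",
        extent=(0, n_times / fs, 0, power.shape[0]),
        **imshow_kw,
    )
    ticks = np.arange(0, power.shape[0], max(1, power.shape[0] // 6))
    ax.set_yticks(ticks + 0.5, [f"{frequencies[i]:g}" for i in ticks])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax


def plot_benchmark(table: pd.DataFrame, summary: str = "argmax", relative: bool = True):
    """Error-vs-SNR panels per regularity level from a benchmark table."""
    import matplotlib.pyplot as plt

    sub = table[table["summary"] == summary]
    sigmas = sorted(sub["sigma_log2"].unique(), reverse=True)
    col = "rel_rms" if relative else "rms"
    fig, axes = plt.subplots(1, len(sigmas), figsize=(3 * len(sigmas), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, sigma in zip(axes, sigmas):
        cell = sub[sub["sigma_log2"] == sigma]
        for name, group in cell.groupby("estimator"):
            group = group.sort_values("snr")
            ax.plot(group["snr"], group[col], marker="o", label=name)
            if not relative:
                ax.fill_between(group["snr"], group["ci_lo"], group["ci_hi"], alpha=0.2)
        ax.set_title(f"sigma = {sigma:g}")
        ax.set_xlabel("SNR")
    axes[0].set_ylabel(f"{'relative ' if relative else ''}RMS error ({summary})")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    return fig
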