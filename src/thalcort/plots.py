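"""Band-power bar charts and PSD line plots for experiment results."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt

from .spectral import BAND_ORDER, SpectrumRecord


def band_power_bars(table, ax=None, title: str = ""):
    """Bar chart of integrated band power, one group per population."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    n_pop = len(table.index)
    width = 0.8 / len(BAND_ORDER)
    for j, band in enumerate(BAND_ORDER):
        xs = [i + j * width for i in range(n_pop)]
        ax.bar(xs, table[band], width=width, label=band)
    ax.set_xticks([i + 0.4 for i in range(n_pop)])
    ax.set_xticklabels(table.index)
    ax.set_ylabel("band power (mV$^2$)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    return ax


def psd_lines(
    spectra: Dict[str, SpectrumRecord],
    ax=None,
    fmax: float = 50.0,
    logy: bool = True,
):
    """Trial-mean power spectral densities, one line per population."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for name, spec in spectra.items():
        m = spec.freqs <= fmax
        ax.plot(spec.freqs[m], spec.psd[m], label=name, lw=1)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (mV$^2$/Hz)")
    ax.legend(fontsize=8)
    return ax
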