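"""Minimal diagnostic plots (optional; requires matplotlib).

The scatter layout mirrors the validation figures: one panel per growth
phase, descriptor on the y-axis against empirical strength on the x-axis,
with the competition/cooperation boundary at strength 1 marked for Mu.
Smoothing, when requested, is presentation only — statistics always come
from :mod:`hawkdove.validation`.
"""

from __future__ import annotations

import numpy as np

from .validation import PHASES, _DESCRIPTOR_TO_STRENGTH


def plot_phase_scatter(table, descriptor="z_mu", log_y=True, lowess=False, ax=None):
    """Scatter of one descriptor vs its empirical strength, split by phase.

    Parameters
    ----------
    table
        The pooled strength/descriptor table from
        :meth:`CocultureResults.table` (columns phase, z_*, Mu/Ag/Al).
    descriptor
        "z_mu", "z_ag" or "z_al".
    lowess
        Overlay a crude running-median trend line (purely cosmetic).

    Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    strength = _DESCRIPTOR_TO_STRENGTH[descriptor]
    phases = [p for p in PHASES if (table["phase"] == p).any()]
    fig, axes = plt.subplots(1, len(phases), figsize=(4 * len(phases), 3.2),
                             sharey=True, squeeze=False)
    for ax_, phase in zip(axes[0], phases):
        sub = table[table["phase"] == phase].dropna(subset=[descriptor, strength])
        ax_.scatter(sub[strength], sub[descriptor], s=12, alpha=0.6)
        if strength == "Mu":
            ax_.axvline(1.0, color="grey", lw=0.8, ls="--")
        if lowess and len(sub) > 10:
            order = np.argsort(sub[strength].to_numpy())
            xs = sub[strength].to_numpy()[order]
            ys = sub[descriptor].to_numpy()[order]
            k = max(len(xs) // 10, 3)
            med = [np.median(ys[max(0, i - k):i + k]) for i in range(len(ys))]
            ax_.plot(xs, med, color="crimson", lw=1.2)
        if log_y:
            ax_.set_yscale("log")
        ax_.set_title(phase)
        ax_.set_xlabel(strength)
    axes[0][0].set_ylabel(descriptor)
    fig.tight_layout()
    return fig
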